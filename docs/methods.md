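# Methods notes

This package implements the downstream community analysis for a soil
bacterial chronosequence — three stand ages (juvenile, young, mature) by
three soil depths (0–10, 10–20, 20–30 cm), one composite sample per cell
— together with a synthetic community generator that supplies data with
the successional structure the analysis assumes. This note records the
models, parameter choices, numerical conventions and known limits.

## Synthetic community model

Counts are Dirichlet-multinomial, the standard overdispersed model for
amplicon data. Per sample:

1. **Stage effect.** Each stage has a mean phylum-proportion vector; the
   effective profile is `(1−δ)·(all-stage mean) + δ·(stage mean)`, with
   the shift effect `δ ∈ [0,1]` (default 1). δ = 0 makes the stages
   exchangeable, which the recovery tests exploit.
2. **Depth effect.** Realized phylum proportions are Dirichlet with
   `α = base_concentration · depth_multiplier · profile`
   (`base_concentration = 100`, depth multipliers `1.0, 0.3, 0.1`).
   Lower concentrations produce less even draws, so expected Shannon
   diversity declines with depth without inventing taxon-specific depth
   biology. E[H] of the Dirichlet mixture is monotone in the
   concentration, which is what the monotonicity tests check.
3. **Within-phylum composition.** OTU proportions inside each phylum are
   a truncated stick-breaking (GEM) draw (`θ = 8`), fixed once per
   dataset so OTU identity is consistent across samples.
4. **Co-occurrence blocks.** All OTUs of a block share a log-normal
   multiplicative factor per sample (`σ` configurable). This aligns the
   block members' abundance *patterns* across samples; it does not shrink
   their raw pairwise distances relative to arbitrary other pairs (a
   shared factor scales differences too), so block structure is assessed
   against the permutation null, not against unrelated pairs.
5. **Counts.** Multinomial with a fixed library size (default 50,000
   reads/sample). Column totals are exact; OTUs with zero total count are
   dropped to keep the table invariant (at least one positive entry per
   row).

The default phylum roster mirrors the seven dominant soil phyla
(Actinobacteria, Proteobacteria, Acidobacteria, Verrucomicrobia,
Planctomycetes, Chloroflexi, Firmicutes ≈ 75–80% of reads) plus six minor
phyla sharing the remainder. Stage means move Actinobacteria from 0.45
(juvenile) to 0.15 (mature) and Proteobacteria from 0.12 to 0.27; the
juvenile profile is the least even, so phylum-level entropy — and with it
OTU-level Shannon diversity — rises with stand age.

What the generator does **not** emulate: taxon-specific depth responses,
phylogenetic correlation, sequencing artifacts (chimeras, singleton
inflation), compositional negative correlations from fixed library size
beyond the multinomial constraint, and environmental covariates. Passing
tests therefore demonstrate the statistical machinery under the stated
model, not field realism.

## Abundance screens

The screen before heat maps and networks keeps a taxon if its relative
abundance reaches 0.5% in at least one in-scope sample; the boundary is
inclusive (≥). For networks the in-scope set is the three depth samples
of one stand. "Most abundant" for the top-50 heat map means highest mean
relative abundance across all samples, ties broken by OTU id. Unassigned
lineages at an aggregation rank pool into an `unclassified` row so column
sums stay exactly 1.

## Group statistics

* **ANOSIM** uses midranks for tied dissimilarities and the scaling
  `n(n−1)/4`. When the number of distinct label arrangements is ≤ 10,000
  the p-value is an exact enumeration (the observed arrangement counts
  itself, so p ≥ 1/N); otherwise uniform label permutations with the
  add-one estimator `(1 + #{R* ≥ R})/(1 + B)`, which can never return 0.
  For the 9-sample, 3-stage design enumeration (1,680 arrangements) is
  always used.
* **SIMPER** operates on relative abundances (composition is what is
  compared); contributions of taxon i for a between pair (j,k) are
  `|x_ij − x_ik| / Σ_m (x_mj + x_mk)`, averaged over all between pairs,
  and sum to the mean between-group Bray-Curtis by construction.
* **Spearman matrices** report midrank ρ with an exact
  permutation-enumeration p for n ≤ 8 and the t approximation above.
* **Heat-map normalization** is a per-row z-score (sample sd, ddof 1);
  rows constant up to floating error become all-zero. Clustering is
  agglomerative complete linkage on Euclidean distances of the normalized
  rows, with a deterministic leaf order (the subtree containing the
  lexicographically smallest label goes left). The dendrogram exports as
  Newick with branch lengths equal to merge-height differences.

## Co-occurrence networks

With three samples per stand, correlation-based inference is unreliable,
so association is scored from the Euclidean distance between OTU
abundance profiles across the stand's depths, mapped to a similarity log
score `s = −ln(d/d_max)` with `d_max` the largest off-diagonal distance.
The transform is monotone-decreasing, so similarity ordering is exactly
reversed distance ordering; the most dissimilar pair scores 0.
Coincident profiles (d = 0) are capped at `−ln(ε/d_max)` with ε the
smallest positive distance, keeping all scores finite. This transform is
one reading of a "similarity log score" of a max-normalized distance; the
matrix builder is small and deliberately replaceable if a different
transform is preferred.

**Thresholding.** The default edge rule keeps pairs at or above the 90th
percentile of off-diagonal scores (moderately dense graphs, hundreds of
edges among tens of nodes); an absolute score threshold is equally
supported.

**Null model.** Each of 1000 iterations independently permutes every
OTU's abundance vector across the stand's samples — preserving the node
set and all marginal abundances while destroying co-variation — then
recomputes scores (with that iteration's own d_max and cap) and counts
edges at an absolute threshold frozen from the observed network. The
observed count is compared to the null distribution by a one-cell
chi-square `(O−E)²/E` (df 1) and by a two-sided empirical p-value
`min(1, 2·min((1+#≥)/(1+B), (1+#≤)/(1+B)))`; the empirical p is
preferred — the chi-square treats the null mean as a Poisson-like
expectation, which the permutation distribution need not satisfy. A
data-permutation null was chosen over Erdős–Rényi graphs because edge
counts must be free to vary while the node set is fixed (otherwise the
"expected edge count" is degenerate); a `G(n, m̄)` generator is provided
separately for topology comparisons.

Two calibration facts shape how the null is used:

* When the threshold is the observed network's own score quantile, the
  observed edge count is by construction the quantile count of its own
  distribution and sits at the centre of the null — the test is then
  conservative for *detecting* structure absence (it still has power
  against real structure, which depresses the null counts). For a
  calibrated type-I test, observed and permuted counts must be
  exchangeable, which holds when the threshold is an absolute score fixed
  in advance; the calibration tests use `s₀ = ln 10` (pairs closer than a
  tenth of the maximal distance), a sparse-density choice comparable to
  the quantile default.
* Extremely strong shared factors can *reduce* power: with three samples
  each row has only 3! = 6 alignment shapes, and permuted
  high-variance rows that land on the same shape become coincidentally
  similar, inflating null edge counts.

**Topology.** Mean local clustering coefficient (degree < 2 ⇒ 0),
average path length over connected pairs only, diameter of the largest
component, and modularity from deterministic greedy (CNM) agglomeration —
chosen over stochastic Louvain-style optimizers for testability. An
edgeless network reports path metrics as missing and Q = 0.

**Keystones.** Normalized betweenness centrality; the top
`⌈0.10 · n⌉` OTUs are flagged, with all boundary ties included and
annotated.

## RDA and variance partitioning

RDA centres both matrices, fits by pseudo-inverse (rank-deficient
predictors degrade to the projection with a warning), and reports
per-axis eigenvalue proportions of total response variance. For a
univariate response the explained proportion equals OLS R² to machine
precision. A Hellinger transform is available and recommended when the
response is an OTU-level composition.

Variance partitioning computes adjusted R² (Ezekiel) for every non-empty
union of the 2–4 explanatory sets, penalizing by the *rank* of the
centred union rather than its column count so collinear unions are not
over-penalized, then solves the linear system `f(S) = Σ_{A∩S≠∅} c(A)`
for the disjoint Venn components `c(A)`. The components sum to the
full-model adjusted R² by construction (to solver precision), and may be
negative — a documented property of adjusted-R² partitioning, never
clipped. Stand age enters as an ordinal 0/1/2 code by default (the
chronosequence is ordered), with one-hot coding behind a flag. When no
environmental table is configured, the pipeline partitions Shannon
diversity between the two factors every dataset has — stage and depth;
with an environmental table, up to four user-defined variable sets.

## Determinism and problem sizes

Every stochastic step takes a seed; the pipeline splits its single seed
per stage by CRC32 of the stage name, so adding a stage never perturbs
the others, and a rerun reproduces the JSON report byte-for-byte.

The statistical test-bench sizes were chosen to give stable rates at
desk scale: the null-model calibration uses 200 exchangeable datasets
(100 OTUs, 3 samples, 5,000 reads) with 199 permutations each; the power
study 100 datasets with four 8-OTU blocks (σ = 2.0, 20,000 reads);
recovery and trend checks use 50–100 seeds of the default generator.
ANOSIM recovery experiments hold the depth concentrations equal so the
stage effect is isolated from the (deliberately strong) depth effect.

## Known limitations

* The similarity log-score transform and the edge threshold are
  interpretive choices; both are parameters, and the quantile/absolute
  duality is exposed everywhere including the null model.
* The empirical null p has resolution 1/(B+1) and, for quantile-frozen
  thresholds, is conservative under no structure (see above).
* SIMPER inherits Bray-Curtis's sensitivity to dominant taxa; no
  standard-deviation ratio per taxon is reported.
* Modularity from greedy agglomeration is a lower bound on the optimum.
* Rarefaction assumes exchangeable reads within a sample; no coverage
  standardization is offered.
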