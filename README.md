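# aldernet

Downstream community analysis for soil bacterial OTU tables from a
forest-succession chronosequence: alpha diversity, group comparison,
distance-based co-occurrence networks with a permutation null model and
keystone-taxon calling, and variance partitioning — together with a
Dirichlet-multinomial community simulator so the whole chain can be
exercised and validated without sequencing data.

## Who this is for

Microbial ecologists with an OTU count table (rows = 16S OTUs with
taxonomy lineages, columns = samples) from a small structured design —
here, three stand ages of *Alnus nepalensis* (juvenile, young, mature)
by three soil depths (0–10, 10–20, 20–30 cm) — who want the standard
succession questions answered reproducibly: does diversity change with
stand age and depth, does composition separate by stage, which taxa drive
the differences, how do co-occurrence networks restructure, and how much
variance do the design factors explain.

## Methods at the core

* **Diversity.** Shannon index `H = −Σ pᵢ log pᵢ`, observed richness, and
  Hurlbert's exact rarefaction `E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]`
  computed with log-gamma arithmetic.
* **ANOSIM.** Rank-based `R = (r̄_between − r̄_within)/(n(n−1)/4)` on
  Bray-Curtis dissimilarities, with an exact enumeration p-value whenever
  the number of distinct label arrangements is ≤ 10,000 (always true for
  the 9-sample design) and a seeded permutation engine otherwise.
* **SIMPER.** Per-taxon decomposition of mean between-group Bray-Curtis;
  contributions sum exactly to the overall dissimilarity.
* **Co-occurrence networks.** With three samples per stand, correlations
  are unstable, so OTU association is scored from the Euclidean distance
  between abundance profiles as a similarity log score
  `s = −ln(d/d_max)`; edges are pairs at or above a score threshold (90th
  percentile by default, or absolute). Topology (nodes, edges, clustering
  coefficient, average path length, diameter, modularity) is summarized
  per stand, robustness is tested against 1000 networks from per-OTU
  abundance permutations (chi-square and empirical p), and OTUs in the
  top betweenness-centrality decile are flagged as keystones.
* **Variance partitioning.** Adjusted-R² (Ezekiel) partitioning of a
  diversity vector or community matrix among 2–4 explanatory sets via
  RDA, solved over the full subset lattice so disjoint components sum to
  the full-model adjusted R² exactly.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic chronosequence (deterministic, seed 1):

```bash
python analysis/01_simulate.py
python analysis/02_diversity.py
python analysis/03_community_comparison.py
python analysis/04_networks.py
python analysis/05_variance_partitioning.py
```

`02_diversity.py` prints

```
Shannon range: 3.96 - 4.76
mean Shannon by stage:
juvenile    4.201
young       4.430
mature      4.668
```

— diversity rises with stand age (and, over many seeds, falls with
depth), the successional signature the simulator is built to carry.
`03_community_comparison.py` reports the stage separation and its drivers:

```
ANOSIM by stage: R = 0.366, p = 0.03571 (exact)
SIMPER juvenile vs mature: 41.6% dissimilarity; top contributor Actinobacteria (36.3%)
```

with Actinobacteria dominance (46.4% juvenile) giving way to
Proteobacteria (20.5% mature). `04_networks.py` summarizes each stand's
network against its null:

```
juvenile: 65 nodes, 208 edges, CC=0.51, APL=3.04, diameter=10, Q=0.51 |
null: expected 155.5 edges, p_emp=0.001998 | 7 keystones, top OTU_0051 (Acidobacteria, BC=0.197)
```

— the observed edge count exceeds the permutation expectation, i.e. the
co-occurrence structure is not explained by marginal abundances. Finally
`05_variance_partitioning.py` splits Shannon-diversity variance between
the design factors (stage unique +0.783, total explained 0.644 here).

The same chain is available as a library (`aldernet.run_pipeline`) and a
CLI (`aldernet all --seed 1 --outdir results`), both of which emit a
byte-reproducible JSON report plus TSV/GraphML/Newick views.

## Layout

```
src/aldernet/      library (io_tables, synthetic, diversity,
                   community_stats, networks, varpart, pipeline, cli)
analysis/          numbered narrative drivers over the library
tests/             unit, property and statistical acceptance tests
scripts/           acceptance.py
docs/methods.md    model and design notes
```
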