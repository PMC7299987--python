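"""Synthetic soil-community generator.

Emulates the statistical structure of a 16S OTU table from an alder
chronosequence (3 stand ages x 3 soil depths): seven dominant phyla holding
~80% of reads, an Actinobacteria -> Proteobacteria dominance shift with
stand age, Shannon diversity falling with depth, and optional blocks of
co-occurring OTUs for network power studies.

Model, per sample:

1. the stage's mean phylum proportions are interpolated between the
   all-stage average and the stage-specific profile by the shift effect
   ``delta`` (delta = 0 makes all stages identical);
2. realized phylum proportions are a Dirichlet draw centred on that mean
   with total concentration ``base_concentration * depth_concentration[d]``
   — smaller concentrations at depth yield less even communities, hence
   lower expected Shannon diversity;
3. OTU proportions within each phylum follow a fixed stick-breaking
   (GEM) profile drawn once per dataset;
4. OTUs of one block share a log-normal multiplicative factor per sample
   (induces co-occurrence across samples);
5. counts are multinomial with a fixed library size.

The Dirichlet-multinomial pairing is the standard overdispersed model for
amplicon counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import DEPTH_BANDS, STAGES, OtuTable, SampleInfo

DOMINANT_PHYLA = (
    "Actinobacteria",
    "Proteobacteria",
    "Acidobacteria",
    "Verrucomicrobia",
    "Planctomycetes",
    "Chloroflexi",
    "Firmicutes",
)

MINOR_PHYLA = (
    "AD3",
    "Nitrospirae",
    "Bacteroidetes",
    "TM7",
    "Gemmatimonadetes",
    "WPS-2",
)

DEFAULT_PHYLA = DOMINANT_PHYLA + MINOR_PHYLA


def _default_stage_means() -> np.ndarray:
    # rows: juvenile, young, mature; dominant seven sum to .80/.78/.75 and
    # the remainder is split evenly over the six minor phyla.
    dominant = np.array(
        [
            [0.45, 0.12, 0.06, 0.05, 0.04, 0.05, 0.03],
            [0.30, 0.20, 0.08, 0.07, 0.05, 0.05, 0.03],
            [0.15, 0.27, 0.10, 0.09, 0.06, 0.05, 0.03],
        ]
    )
    rest = 1.0 - dominant.sum(axis=1, keepdims=True)
    minors = np.repeat(rest / len(MINOR_PHYLA), len(MINOR_PHYLA), axis=1)
    return np.hstack([dominant, minors])


@dataclass
class SuccessionConfig:
    """Parameters of the chronosequence community generator."""

    phyla: Sequence[str] = DEFAULT_PHYLA
    n_otus_per_phylum: int = 25
    phylum_stage_means: np.ndarray = field(default_factory=_default_stage_means)
    shift_effect: float = 1.0  # delta in [0, 1]
    depth_concentration: Sequence[float] = (1.0, 0.3, 0.1)
    base_concentration: float = 100.0
    stick_breaking_theta: float = 8.0
    reads_per_sample: int = 50_000
    block_structure: Sequence[Sequence[int]] = ()
    block_sigma: float = 1.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.phylum_stage_means = np.asarray(self.phylum_stage_means, dtype=float)
        if self.phylum_stage_means.shape != (len(STAGES), len(self.phyla)):
            raise ValueError(
                "phylum_stage_means must be "
                f"{(len(STAGES), len(self.phyla))}, got "
                f"{self.phylum_stage_means.shape}"
            )
        sums = self.phylum_stage_means.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"stage phylum means must sum to 1, got {sums}")
        if not 0.0 <= self.shift_effect <= 1.0:
            raise ValueError("shift_effect must lie in [0, 1]")
        if len(self.depth_concentration) != len(DEPTH_BANDS):
            raise ValueError(
                f"depth_concentration needs {len(DEPTH_BANDS)} entries"
            )
        if min(self.depth_concentration) <= 0:
            raise ValueError("depth_concentration must be strictly positive")
        n_total = self.n_otus_per_phylum * len(self.phyla)
        for block in self.block_structure:
            for idx in block:
                if not 0 <= idx < n_total:
                    raise ValueError(
                        f"block OTU index {idx} outside [0, {n_total})"
                    )

    @property
    def n_otus(self) -> int:
        return self.n_otus_per_phylum * len(self.phyla)


def _stick_breaking(rng: np.random.Generator, k: int, theta: float) -> np.ndarray:
    """Truncated GEM(theta) weights, renormalized to sum to 1."""
    v = rng.beta(1.0, theta, size=k)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    w = v * remaining
    return w / w.sum()


def generate_succession_dataset(config: SuccessionConfig) -> OtuTable:
    """Draw one OTU table for the 3-stage x 3-depth design.

    Identical configs (including seed) give identical tables.  OTUs that end
    up with zero counts in every sample are dropped (the table invariant
    requires one positive entry per retained OTU).
    """
    rng = np.random.default_rng(config.seed)
    n_phyla = len(config.phyla)
    k = config.n_otus_per_phylum
    n_otus = config.n_otus

    width = max(4, len(str(n_otus)))
    otu_ids = [f"OTU_{i + 1:0{width}d}" for i in range(n_otus)]
    phylum_of = np.repeat(np.arange(n_phyla), k)
    lineages = pd.Series(
        [f"k__Bacteria;p__{config.phyla[p]}" for p in phylum_of],
        index=otu_ids,
        name="taxonomy",
    )

    # fixed within-phylum composition, one draw per dataset
    within = np.zeros(n_otus)
    for p in range(n_phyla):
        within[p * k : (p + 1) * k] = _stick_breaking(
            rng, k, config.stick_breaking_theta
        )

    mean_profile = config.phylum_stage_means.mean(axis=0)
    delta = config.shift_effect

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleInfo] = []
    for si, stage in enumerate(STAGES):
        stage_mean = (1.0 - delta) * mean_profile + delta * config.phylum_stage_means[
            si
        ]
        for di, depth in enumerate(DEPTH_BANDS):
            for rep in range(config.n_replicates):
                alpha = (
                    config.base_concentration
                    * config.depth_concentration[di]
                    * stage_mean
                )
                phylum_props = rng.dirichlet(alpha)
                p_otu = phylum_props[phylum_of] * within
                if config.block_structure:
                    for block in config.block_structure:
                        factor = np.exp(config.block_sigma * rng.normal())
                        p_otu[list(block)] *= factor
                p_otu = p_otu / p_otu.sum()
                counts = rng.multinomial(config.reads_per_sample, p_otu)
                sid = f"{stage}_{depth}"
                if config.n_replicates > 1:
                    sid = f"{sid}_r{rep + 1}"
                columns[sid] = counts
                samples.append(
                    SampleInfo(
                        sample_id=sid, stage=stage, depth_band=depth, replicate=rep
                    )
                )

    counts = pd.DataFrame(columns, index=otu_ids, dtype=np.int64)
    nonzero = counts.sum(axis=1) > 0
    return OtuTable(
        counts=counts.loc[nonzero],
        taxonomy=lineages.loc[nonzero],
        samples=samples,
    )


def generate_null_dataset(
    n_otus: int, n_samples: int, reads: int, seed: int
) -> OtuTable:
    """Exchangeable-sample null community: no group or block structure.

    Every sample is an i.i.d. multinomial draw from one fixed proportion
    vector (itself drawn once from a flat Dirichlet), so any sample
    labelling is arbitrary — the type-I-error benchmark for the group and
    network tests.
    """
    if min(n_otus, n_samples, reads) <= 0:
        raise ValueError("n_otus, n_samples and reads must be positive")
    rng = np.random.default_rng(seed)
    proportions = rng.dirichlet(np.ones(n_otus))
    width = max(4, len(str(n_otus)))
    otu_ids = [f"OTU_{i + 1:0{width}d}" for i in range(n_otus)]
    sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]
    counts = pd.DataFrame(
        rng.multinomial(reads, proportions, size=n_samples).T,
        index=otu_ids,
        columns=sample_ids,
        dtype=np.int64,
    )
    taxonomy = pd.Series("k__Bacteria", index=otu_ids, name="taxonomy")
    nonzero = counts.sum(axis=1) > 0
    samples = [SampleInfo(sample_id=s) for s in sample_ids]
    return OtuTable(
        counts=counts.loc[nonzero], taxonomy=taxonomy.loc[nonzero], samples=samples
    )
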