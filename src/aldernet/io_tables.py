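"""OTU table input/output and abundance bookkeeping.

The universal input of the pipeline is an OTU count table: rows are
operational taxonomic units (16S clusters at 97% identity) carrying a
taxonomy lineage string, columns are soil samples from a stand-age x
soil-depth design.  This module reads and writes that table as plain TSV,
converts counts to relative abundances, aggregates to higher taxonomic
ranks, and applies the abundance screens used before heat-map and network
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k__": "kingdom",
    "d__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}

STAGES = ("juvenile", "young", "mature")
DEPTH_BANDS = ("0-10", "10-20", "20-30")

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one soil sample.

    ``stage`` and ``depth_band`` may be None for datasets without the
    chronosequence design (e.g. exchangeable null communities).
    ``replicate`` distinguishes multiple samples of one (stage, depth) cell.
    """

    sample_id: str
    stage: str | None = None
    depth_band: str | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r} for sample {self.sample_id!r}; "
                f"expected one of {STAGES}"
            )
        if self.depth_band is not None and self.depth_band not in DEPTH_BANDS:
            raise ValueError(
                f"unknown depth band {self.depth_band!r} for sample "
                f"{self.sample_id!r}; expected one of {DEPTH_BANDS}"
            )


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-separated lineage into a rank -> name mapping.

    Accepts both Greengenes-style prefixed fields (``k__Bacteria;p__...``)
    and plain positional lineages (``Bacteria;Actinobacteria;...``).
    Empty fields (``p__`` with no name) are treated as unassigned.
    """
    out: dict[str, str] = {}
    fields = [f.strip() for f in lineage.split(";")]
    positional_rank = 0
    for f in fields:
        if not f:
            positional_rank += 1
            continue
        prefix = f[:3]
        if prefix in _PREFIX_TO_RANK:
            name = f[3:].strip()
            if name:
                out[_PREFIX_TO_RANK[prefix]] = name
            positional_rank += 1
        else:
            if positional_rank < len(RANKS):
                out[RANKS[positional_rank]] = f
            positional_rank += 1
    return out


@dataclass
class OtuTable:
    """Integer count matrix (OTU x sample) with taxonomy and sample metadata.

    Invariants (enforced on construction):

    * counts are non-negative integers with at least one positive entry per OTU;
    * OTU ids unique; every counts column has exactly one SampleInfo;
    * (stage, depth_band, replicate) unique among fully labelled samples.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    samples: list[SampleInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
            object.__setattr__(self, "counts", counts)
            values = counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at OTU {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        empty = values.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"OTUs with no positive count: {counts.index[empty].tolist()}"
            )
        if not self.taxonomy.index.equals(counts.index):
            raise ValueError("taxonomy index must match counts index")
        ids = {s.sample_id for s in self.samples}
        if len(ids) != len(self.samples):
            raise ValueError("duplicate sample_id in metadata")
        missing = [c for c in counts.columns if c not in ids]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        labelled = [
            (s.stage, s.depth_band, s.replicate)
            for s in self.samples
            if s.stage is not None and s.depth_band is not None
        ]
        if len(labelled) != len(set(labelled)):
            raise ValueError("(stage, depth_band, replicate) must be unique")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_info(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_for_stage(self, stage: str) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.stage == stage and s.sample_id in self.counts.columns
        ]


@dataclass
class AbundanceProfile:
    """Relative abundances (fractions) of taxa per sample.

    ``rank`` records the taxonomic level of the rows ("otu" or one of RANKS).
    ``lineages`` carries the per-row lineage strings when rows are OTUs, so the
    profile can be aggregated further or annotated on network nodes.
    Full (unfiltered) profiles have columns summing to 1; screened profiles
    keep the fractions of the surviving rows unchanged.
    """

    values: pd.DataFrame
    rank: str = "otu"
    lineages: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("abundance fractions must lie in [0, 1]")
        if self.lineages is not None and not self.lineages.index.equals(
            self.values.index
        ):
            raise ValueError("lineages index must match values index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceProfile":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return AbundanceProfile(
            values=self.values.loc[:, list(sample_ids)].copy(),
            rank=self.rank,
            lineages=None if self.lineages is None else self.lineages.copy(),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_HEADER_FIRST = "#OTU_ID"
_HEADER_LAST = "taxonomy"


def read_otu_table(path, metadata=None) -> OtuTable:
    """Read a TSV OTU table (``#OTU_ID<TAB>samples...<TAB>taxonomy``).

    ``metadata`` is either a path to a metadata TSV or a list of SampleInfo;
    if omitted, samples get empty (None) stage/depth metadata.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != _HEADER_FIRST or header[-1] != _HEADER_LAST:
            raise ValueError(
                f"{path}: expected header '{_HEADER_FIRST}<TAB>sample...<TAB>"
                f"{_HEADER_LAST}', got {header[:3]}..."
            )
        sample_ids = header[1:-1]
        otu_ids: list[str] = []
        rows: list[list[int]] = []
        lineages: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            otu_ids.append(fields[0])
            row = []
            for j, cell in enumerate(fields[1:-1]):
                try:
                    value = int(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed count {cell!r} in "
                        f"column {sample_ids[j]!r} (OTU {fields[0]!r})"
                    ) from exc
                row.append(value)
            rows.append(row)
            lineages.append(fields[-1])
    counts = pd.DataFrame(rows, index=otu_ids, columns=sample_ids, dtype=np.int64)
    taxonomy = pd.Series(lineages, index=otu_ids, name="taxonomy")
    if metadata is None:
        samples = [SampleInfo(sample_id=s) for s in sample_ids]
    elif isinstance(metadata, (list, tuple)):
        samples = list(metadata)
    else:
        samples = read_metadata(metadata)
    return OtuTable(counts=counts, taxonomy=taxonomy, samples=samples)


def write_otu_table(table: OtuTable, path) -> None:
    """Write the table in the same TSV dialect ``read_otu_table`` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([_HEADER_FIRST, *table.sample_ids, _HEADER_LAST]) + "\n")
        values = table.counts.to_numpy()
        for i, otu in enumerate(table.otu_ids):
            cells = "\t".join(str(int(v)) for v in values[i])
            fh.write(f"{otu}\t{cells}\t{table.taxonomy.iloc[i]}\n")


def read_metadata(path) -> list[SampleInfo]:
    """Read sample metadata TSV (sample_id, stage, depth_band[, replicate])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "depth_band"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        rep = int(row["replicate"]) if "replicate" in df.columns else 0
        stage = row["stage"] if pd.notna(row["stage"]) else None
        depth = row["depth_band"] if pd.notna(row["depth_band"]) else None
        out.append(
            SampleInfo(
                sample_id=row["sample_id"], stage=stage, depth_band=depth,
                replicate=rep,
            )
        )
    return out


def write_metadata(samples: Iterable[SampleInfo], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "stage": s.stage if s.stage is not None else "",
                "depth_band": s.depth_band if s.depth_band is not None else "",
                "replicate": s.replicate,
            }
            for s in samples
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# abundance operations
# ---------------------------------------------------------------------------


def relative_abundance(table: OtuTable) -> AbundanceProfile:
    """Convert counts to per-sample fractions (each column sums to 1)."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero.index)}")
    values = table.counts / totals
    return AbundanceProfile(
        values=values.astype(float), rank="otu", lineages=table.taxonomy.copy()
    )


def aggregate_by_rank(profile: AbundanceProfile, rank: str) -> AbundanceProfile:
    """Pool OTU fractions to one row per taxon at ``rank``.

    OTUs with no assignment at ``rank`` are pooled into an "unclassified"
    row so that column sums are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if profile.lineages is None:
        raise ValueError("profile has no lineages; aggregate from an OTU profile")
    names = [
        parse_lineage(lin).get(rank, UNCLASSIFIED) for lin in profile.lineages
    ]
    if all(n == UNCLASSIFIED for n in names):
        raise ValueError(f"no OTU carries an assignment at rank {rank!r}")
    grouped = profile.values.groupby(pd.Index(names, name=rank), sort=True).sum()
    return AbundanceProfile(values=grouped, rank=rank, lineages=None)


def filter_by_abundance(
    profile: AbundanceProfile,
    samples_in_scope: Sequence[str] | None = None,
    threshold: float = 0.005,
    mode: str = "any_sample",
) -> AbundanceProfile:
    """Keep rows reaching ``threshold`` in at least one in-scope sample.

    The boundary is inclusive: a row exactly at the threshold is kept.  For
    network construction the in-scope samples are the three depth samples of
    one stand; by default all samples are in scope.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if mode != "any_sample":
        raise ValueError(f"unknown mode {mode!r}")
    scope = list(profile.values.columns) if samples_in_scope is None else list(
        samples_in_scope
    )
    if not scope:
        raise ValueError("samples_in_scope must be non-empty")
    missing = [s for s in scope if s not in profile.values.columns]
    if missing:
        raise KeyError(f"unknown samples in scope: {missing}")
    keep = (profile.values.loc[:, scope] >= threshold).any(axis=1)
    return AbundanceProfile(
        values=profile.values.loc[keep].copy(),
        rank=profile.rank,
        lineages=None if profile.lineages is None else profile.lineages.loc[keep],
    )


def top_n_otus(profile: AbundanceProfile, n: int = 50) -> AbundanceProfile:
    """The ``n`` most abundant rows by mean fraction across all samples.

    Rows are returned sorted by descending mean; ties broken by ascending
    row id so the selection is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    means = profile.values.mean(axis=1)
    order = sorted(profile.values.index, key=lambda i: (-means[i], i))
    chosen = order[: min(n, len(order))]
    return AbundanceProfile(
        values=profile.values.loc[chosen].copy(),
        rank=profile.rank,
        lineages=None
        if profile.lineages is None
        else profile.lineages.loc[chosen],
    )
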