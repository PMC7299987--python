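#!/usr/bin/env python
"""Variance partitioning of Shannon diversity between design factors.

Partitions the adjusted R^2 of per-sample Shannon diversity between stand
age and soil depth (both ordinal-coded), reporting unique and shared
components and the residual.  Writes results/varpart/varpart.tsv.
"""

import importlib
from pathlib import Path

from aldernet.diversity import diversity_table
from aldernet.varpart import encode_depth, encode_stage, variance_partition

ROOT = Path(__file__).resolve().parent.parent / "results"
load_table = importlib.import_module("02_diversity").load_table


def main() -> None:
    table = load_table()
    div = diversity_table(table)
    info = {s.sample_id: s for s in table.samples}
    sample_ids = div["sample_id"].tolist()
    x_sets = {
        "stage": encode_stage([info[s].stage for s in sample_ids]),
        "depth": encode_depth([info[s].depth_band for s in sample_ids]),
    }
    vp = variance_partition(div["shannon"].to_numpy(), x_sets)
    outdir = ROOT / "varpart"
    outdir.mkdir(parents=True, exist_ok=True)
    vp.component_table().to_csv(outdir / "varpart.tsv", sep="\t", index=False)
    print("adjusted R^2 components of Shannon diversity:")
    for _, row in vp.component_table().iterrows():
        print(f"  {row['component']}: {row['adj_r2']:+.3f}")
    print(f"  total explained: {vp.total_explained:.3f}")


if __name__ == "__main__":
    main()
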