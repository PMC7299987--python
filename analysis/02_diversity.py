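#!/usr/bin/env python
"""Alpha diversity of the simulated chronosequence.

Computes per-sample richness and Shannon diversity plus exact rarefaction
curves, writes them under results/diversity/, and prints the stage and
depth trends.
"""

from pathlib import Path

from aldernet.diversity import diversity_table, rarefaction_table
from aldernet.io_tables import DEPTH_BANDS, STAGES, read_otu_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_table():
    table_path = ROOT / "synthetic" / "otu_table.tsv"
    if not table_path.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    return read_otu_table(table_path, metadata=ROOT / "synthetic" / "metadata.tsv")


def main() -> None:
    table = load_table()
    div = diversity_table(table)
    rare = rarefaction_table(table)
    outdir = ROOT / "diversity"
    outdir.mkdir(parents=True, exist_ok=True)
    div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    rare.to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)

    info = {s.sample_id: s for s in table.samples}
    div["stage"] = [info[s].stage for s in div["sample_id"]]
    div["depth"] = [info[s].depth_band for s in div["sample_id"]]
    print(f"Shannon range: {div['shannon'].min():.2f} - {div['shannon'].max():.2f}")
    by_stage = div.groupby("stage")["shannon"].mean().reindex(list(STAGES))
    by_depth = div.groupby("depth")["shannon"].mean().reindex(list(DEPTH_BANDS))
    print("mean Shannon by stage:")
    print(by_stage.round(3).to_string())
    print("mean Shannon by depth (cm):")
    print(by_depth.round(3).to_string())


if __name__ == "__main__":
    main()
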