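#!/usr/bin/env python
"""Generate the synthetic chronosequence OTU table used by the analyses.

Draws the default 3-stage x 3-depth soil community (13 phyla, 25 OTUs per
phylum, 50,000 reads per sample) and writes it, with its sample metadata,
under results/synthetic/.
"""

from pathlib import Path

from aldernet.io_tables import write_metadata, write_otu_table
from aldernet.pipeline import stage_seed
from aldernet.synthetic import SuccessionConfig, generate_succession_dataset

SEED = 1
OUTDIR = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    config = SuccessionConfig(seed=stage_seed(SEED, "simulate"))
    table = generate_succession_dataset(config)
    OUTDIR.mkdir(parents=True, exist_ok=True)
    write_otu_table(table, OUTDIR / "otu_table.tsv")
    write_metadata(table.samples, OUTDIR / "metadata.tsv")
    totals = table.counts.sum(axis=0)
    print(
        f"wrote {len(table.otu_ids)} OTUs x {len(table.sample_ids)} samples "
        f"({int(totals.iloc[0])} reads/sample) to {OUTDIR}"
    )


if __name__ == "__main__":
    main()
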