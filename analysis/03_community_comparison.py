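#!/usr/bin/env python
"""Community composition shifts across stand ages.

Phylum composition per stage, ANOSIM (Bray-Curtis, grouped by stand age),
phylum-level SIMPER for every stage pair, and the top-50-OTU heat-map
clustering (row z-scores, complete linkage) with its dendrogram in Newick.
Outputs under results/comparison/.
"""

import importlib
from pathlib import Path

from aldernet.community_stats import (
    anosim,
    bray_curtis,
    heatmap_matrix,
    linkage_to_newick,
    simper,
)
from aldernet.io_tables import (
    STAGES,
    aggregate_by_rank,
    filter_by_abundance,
    relative_abundance,
    top_n_otus,
)
from aldernet.pipeline import stage_seed

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"
load_table = importlib.import_module("02_diversity").load_table


def main() -> None:
    table = load_table()
    outdir = ROOT / "comparison"
    outdir.mkdir(parents=True, exist_ok=True)

    profile = relative_abundance(table)
    phyla = aggregate_by_rank(profile, "phylum")
    stage_of = {s.sample_id: s.stage for s in table.samples}

    print("mean phylum share per stage (top 5):")
    for stage in STAGES:
        cols = table.samples_for_stage(stage)
        means = phyla.values[cols].mean(axis=1).sort_values(ascending=False)
        top = ", ".join(f"{k} {100 * v:.1f}%" for k, v in means.head(5).items())
        print(f"  {stage}: {top}")

    dm = bray_curtis(profile)
    res = anosim(dm, {sid: stage_of[sid] for sid in dm.ids},
                 seed=stage_seed(SEED, "anosim"))
    print(f"ANOSIM by stage: R = {res.r:.3f}, p = {res.p:.4g} ({res.method})")

    for i, a in enumerate(STAGES):
        for b in STAGES[i + 1:]:
            sim = simper(phyla, stage_of, pair=(a, b))
            sim.contributions.to_csv(
                outdir / f"simper_{a}_vs_{b}.tsv", sep="\t", index=False
            )
            lead = sim.contributions.iloc[0]
            print(
                f"SIMPER {a} vs {b}: {100 * sim.overall_dissimilarity:.1f}% "
                f"dissimilarity; top contributor {lead['taxon']} "
                f"({lead['percent']:.1f}%)"
            )

    top50 = top_n_otus(filter_by_abundance(profile), n=50)
    heat = heatmap_matrix(top50)
    heat.matrix.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    (outdir / "dendrogram.nwk").write_text(
        linkage_to_newick(heat.row_linkage, list(top50.values.index)) + "\n"
    )
    print(f"heat-map rows clustered; leaf order starts {heat.row_order[:3]}")


if __name__ == "__main__":
    main()
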