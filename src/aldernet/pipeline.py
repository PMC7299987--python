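"""End-to-end pipeline: load/simulate -> diversity -> ANOSIM/SIMPER ->
heat-map clustering -> per-stand networks with nulls and keystones ->
variance partitioning.

One top-level seed is split deterministically per stage (CRC32 of the stage
name XOR seed), so adding a stage never perturbs the randomness of the
others, and a rerun with the same config reproduces the JSON report
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_stats import (
    HeatmapResult,
    anosim,
    bray_curtis,
    heatmap_matrix,
    linkage_to_newick,
    simper,
)
from .diversity import diversity_table, rarefaction_table
from .io_tables import (
    STAGES,
    OtuTable,
    aggregate_by_rank,
    filter_by_abundance,
    read_metadata,
    read_otu_table,
    relative_abundance,
    top_n_otus,
)
from .networks import (
    KeystoneReport,
    build_network,
    keystones,
    node_attributes_from_profile,
    null_edge_distribution,
    similarity_log_scores,
    topology,
    write_edge_list,
    write_graphml,
    write_node_table,
)
from .synthetic import SuccessionConfig, generate_succession_dataset
from .varpart import encode_depth, encode_stage, variance_partition

logger = logging.getLogger("aldernet")


def stage_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the pipeline seed."""
    return (zlib.crc32(name.encode("utf-8")) ^ seed) % (2**31)


@dataclass
class PipelineConfig:
    otu_table_path: str | None = None
    metadata_path: str | None = None
    env_table_path: str | None = None
    synthetic: SuccessionConfig | None = None
    abundance_threshold: float = 0.005
    top_n: int = 50
    network_quantile: float | None = 0.9
    network_absolute: float | None = None
    null_iterations: int = 1000
    anosim_permutations: int = 9999
    shannon_base: str = "e"
    varpart_sets: dict[str, list[str]] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = SuccessionConfig(**synth)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.synthetic is not None:
            synth = dataclasses.asdict(self.synthetic)
            synth["phyla"] = list(synth["phyla"])
            synth["phylum_stage_means"] = np.asarray(
                synth["phylum_stage_means"]
            ).tolist()
            synth["depth_concentration"] = list(synth["depth_concentration"])
            synth["block_structure"] = [list(b) for b in synth["block_structure"]]
            out["synthetic"] = synth
        return out


@dataclass
class PipelineResult:
    report: dict
    table: OtuTable
    heatmap: HeatmapResult
    networks: dict[str, nx.Graph]
    keystone_reports: dict[str, KeystoneReport]
    diversity: pd.DataFrame
    rarefaction: pd.DataFrame
    simper_tables: dict[str, pd.DataFrame]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_table(config: PipelineConfig) -> OtuTable:
    if config.otu_table_path is not None:
        if config.metadata_path is None:
            raise FileNotFoundError("metadata_path required with otu_table_path")
        meta = Path(config.metadata_path)
        if not meta.exists():
            raise FileNotFoundError(f"metadata file not found: {meta}")
        table_path = Path(config.otu_table_path)
        if not table_path.exists():
            raise FileNotFoundError(f"OTU table not found: {table_path}")
        return read_otu_table(table_path, metadata=read_metadata(meta))
    synth = config.synthetic or SuccessionConfig()
    synth = dataclasses.replace(synth, seed=stage_seed(config.seed, "simulate"))
    return generate_succession_dataset(synth)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all analysis stages in dependency order."""
    stage = "load"
    try:
        table = _load_table(config)
        logger.info("loaded table: %d OTUs x %d samples",
                    len(table.otu_ids), len(table.sample_ids))

        stage = "diversity"
        div = diversity_table(table, base=config.shannon_base)
        rare = rarefaction_table(table, n_points=8)

        stage = "composition"
        profile = relative_abundance(table)
        phylum_profile = aggregate_by_rank(profile, "phylum")
        stage_means = {}
        for st in STAGES:
            cols = table.samples_for_stage(st)
            if cols:
                stage_means[st] = phylum_profile.values[cols].mean(axis=1)
        dominant = {
            st: str(means.idxmax()) for st, means in stage_means.items()
        }

        stage = "anosim"
        stage_of = {s.sample_id: s.stage for s in table.samples}
        dm = bray_curtis(profile)
        ano = anosim(
            dm,
            {sid: stage_of[sid] for sid in dm.ids},
            n_permutations=config.anosim_permutations,
            seed=stage_seed(config.seed, "anosim"),
        )

        stage = "simper"
        simper_tables: dict[str, pd.DataFrame] = {}
        simper_report = {}
        stages_present = [st for st in STAGES if table.samples_for_stage(st)]
        for i, a in enumerate(stages_present):
            for b in stages_present[i + 1:]:
                res = simper(phylum_profile, stage_of, pair=(a, b))
                key = f"{a}_vs_{b}"
                simper_tables[key] = res.contributions
                simper_report[key] = {
                    "overall_dissimilarity": res.overall_dissimilarity,
                    "top_taxa": res.contributions.head(10).to_dict("records"),
                }

        stage = "heatmap"
        screened = filter_by_abundance(
            profile, threshold=config.abundance_threshold
        )
        top = top_n_otus(screened, n=config.top_n)
        heat = heatmap_matrix(top)
        newick = linkage_to_newick(heat.row_linkage, list(top.values.index))

        stage = "networks"
        nets: dict[str, nx.Graph] = {}
        keyrep: dict[str, KeystoneReport] = {}
        net_report = {}
        for st in stages_present:
            cols = table.samples_for_stage(st)
            stand = filter_by_abundance(
                profile,
                samples_in_scope=cols,
                threshold=config.abundance_threshold,
            ).subset_samples(cols)
            sim = similarity_log_scores(stand)
            phyla, medians = node_attributes_from_profile(stand)
            g = build_network(
                sim,
                quantile=config.network_quantile,
                absolute=config.network_absolute,
                node_phylum=phyla,
                node_abundance=medians,
                stage=st,
            )
            topo = topology(g)
            null = null_edge_distribution(
                stand,
                quantile=config.network_quantile,
                absolute=config.network_absolute,
                n_iterations=config.null_iterations,
                seed=stage_seed(config.seed, f"null_{st}"),
            )
            keys = keystones(g)
            nets[st] = g
            keyrep[st] = keys
            net_report[st] = {
                "topology": dataclasses.asdict(topo),
                "null_model": {
                    "observed_edges": null.observed_edges,
                    "expected_edges": null.expected_edges,
                    "chi_square": null.chi_square,
                    "p_chi": null.p_chi,
                    "p_empirical": null.p_empirical,
                    "threshold": null.threshold,
                    "n_iterations": null.n_iterations,
                    "seed": null.seed,
                },
                "keystones": keys.table[keys.table["keystone"]].to_dict(
                    "records"
                ),
                "boundary_tie": keys.boundary_tie,
            }

        stage = "varpart"
        sample_ids = div["sample_id"].tolist()
        info = {s.sample_id: s for s in table.samples}
        shannon_vec = div["shannon"].to_numpy()
        if config.env_table_path and config.varpart_sets:
            env = pd.read_csv(config.env_table_path, sep="\t", index_col=0)
            env = env.loc[sample_ids]
            x_sets = {
                name: env[cols].to_numpy()
                for name, cols in config.varpart_sets.items()
            }
            x_sets["stage"] = encode_stage(
                [info[s].stage for s in sample_ids]
            )
        else:
            x_sets = {
                "stage": encode_stage([info[s].stage for s in sample_ids]),
                "depth": encode_depth([info[s].depth_band for s in sample_ids]),
            }
        vp = variance_partition(shannon_vec, x_sets)

        report = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "n_otus": len(table.otu_ids),
            "n_samples": len(table.sample_ids),
            "diversity": div.to_dict("records"),
            "phylum_stage_means": {
                st: {str(k): float(v) for k, v in means.items()}
                for st, means in stage_means.items()
            },
            "dominant_phylum": dominant,
            "anosim": dataclasses.asdict(ano),
            "simper": simper_report,
            "heatmap": {
                "row_order": heat.row_order,
                "col_order": heat.col_order,
                "newick": newick,
            },
            "networks": net_report,
            "varpart": {
                "sets": list(x_sets),
                "components": {
                    "&".join(sorted(k)): v for k, v in vp.components.items()
                },
                "unique": vp.unique,
                "total_explained": vp.total_explained,
                "residual": vp.residual,
            },
            "seeds": {
                name: stage_seed(config.seed, name)
                for name in ["simulate", "anosim"]
                + [f"null_{st}" for st in stages_present]
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        report=report,
        table=table,
        heatmap=heat,
        networks=nets,
        keystone_reports=keyrep,
        diversity=div,
        rarefaction=rare,
        simper_tables=simper_tables,
    )


def export_all(result: PipelineResult, outdir) -> list[Path]:
    """Write the JSON report and its TSV/GraphML/Newick views."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(path: Path, fn) -> None:
        fn(path)
        written.append(path)

    _write(outdir / "diversity.tsv",
           lambda p: result.diversity.to_csv(p, sep="\t", index=False))
    _write(outdir / "rarefaction.tsv",
           lambda p: result.rarefaction.to_csv(p, sep="\t", index=False))
    for key, frame in result.simper_tables.items():
        _write(outdir / f"simper_{key}.tsv",
               lambda p, fr=frame: fr.to_csv(p, sep="\t", index=False))
    _write(outdir / "heatmap_matrix.tsv",
           lambda p: result.heatmap.matrix.to_csv(p, sep="\t"))
    _write(outdir / "dendrogram.nwk",
           lambda p: p.write_text(result.report["heatmap"]["newick"] + "\n"))
    for st, g in result.networks.items():
        _write(outdir / f"network_{st}.graphml",
               lambda p, gg=g: write_graphml(gg, p))
        _write(outdir / f"network_{st}_edges.tsv",
               lambda p, gg=g: write_edge_list(gg, p))
        _write(
            outdir / f"network_{st}_nodes.tsv",
            lambda p, gg=g, kr=result.keystone_reports[st]: write_node_table(
                gg, kr, p
            ),
        )
    vp = result.report["varpart"]
    vp_frame = pd.DataFrame(
        [{"component": k, "adj_r2": v} for k, v in vp["components"].items()]
        + [{"component": "residual", "adj_r2": vp["residual"]}]
    )
    _write(outdir / "varpart.tsv",
           lambda p: vp_frame.to_csv(p, sep="\t", index=False))
    _write(
        outdir / "report.json",
        lambda p: p.write_text(
            json.dumps(
                result.report, indent=2, sort_keys=True, default=_json_default
            )
            + "\n"
        ),
    )
    return written
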