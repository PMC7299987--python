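"""Euclidean log-score co-occurrence networks, nulls and keystone taxa.

Correlation-based co-occurrence inference is unreliable with only three
samples per stand, so association between OTUs is scored directly from the
Euclidean distance between their abundance profiles across a stand's depth
samples.  Distances are mapped to a similarity "log score"

    s_jk = -ln(d_jk / d_max),

where d_max is the largest off-diagonal distance: the most dissimilar pair
scores 0 and closer pairs score higher, unboundedly.  Coincident profiles
(d = 0) are capped at the score of the smallest positive distance so all
scores stay finite.  An edge connects two OTUs when their score reaches a
threshold (a score quantile by default, or an absolute score).

Robustness is assessed against a data-permutation null: each OTU's
abundance vector is independently shuffled across the stand's samples —
preserving the node set and every OTU's marginal abundances while
destroying co-variation — and the network is rebuilt with the threshold
frozen from the observed network.  The observed edge count is compared to
the null edge-count distribution by a one-cell chi-square and by a
two-sided empirical permutation p-value (preferred).

Keystone taxa are OTUs whose normalized betweenness centrality lies in the
top decile of their network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as ss
from scipy.spatial.distance import pdist, squareform

from .io_tables import AbundanceProfile, parse_lineage


@dataclass
class SimilarityMatrix:
    ids: list[str]
    scores: np.ndarray  # symmetric, non-negative, zero diagonal
    d_max: float
    epsilon: float  # smallest positive distance
    cap: float  # score assigned to coincident profiles


def _scores_from_values(values: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Distance -> log-score transform shared by observed and null paths."""
    condensed = pdist(values, metric="euclidean")
    d_max = condensed.max() if len(condensed) else 0.0
    if d_max <= 0:
        raise ValueError("all pairwise distances are zero; degenerate stand")
    positive = condensed[condensed > 0]
    epsilon = positive.min()
    cap = -math.log(epsilon / d_max)
    scores = np.where(condensed > 0, -np.log(np.maximum(condensed, 1e-300) / d_max), cap)
    return squareform(scores, checks=False), d_max, epsilon, cap


def similarity_log_scores(profile: AbundanceProfile) -> SimilarityMatrix:
    """Similarity log scores between OTU rows of a stand-restricted profile.

    The profile should already have passed the 0.5% within-stand abundance
    screen and be restricted to the stand's (>= 2) samples.
    """
    if profile.values.shape[1] < 2:
        raise ValueError("need at least two samples (the stand's depths)")
    if profile.values.shape[0] < 2:
        raise ValueError("need at least two OTUs")
    scores, d_max, eps, cap = _scores_from_values(profile.values.to_numpy())
    return SimilarityMatrix(
        ids=list(profile.values.index),
        scores=scores,
        d_max=float(d_max),
        epsilon=float(eps),
        cap=float(cap),
    )


def _resolve_threshold(
    scores: np.ndarray, quantile: float | None, absolute: float | None
) -> float:
    if (quantile is None) == (absolute is None):
        raise ValueError("specify exactly one of quantile= or absolute=")
    if absolute is not None:
        return float(absolute)
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    iu = np.triu_indices(scores.shape[0], k=1)
    return float(np.quantile(scores[iu], quantile))


def build_network(
    sim: SimilarityMatrix,
    quantile: float | None = 0.9,
    absolute: float | None = None,
    node_phylum: dict[str, str] | None = None,
    node_abundance: dict[str, float] | None = None,
    stage: str | None = None,
) -> nx.Graph:
    """Threshold a similarity matrix into an undirected OTU network.

    Edge iff score >= threshold (the ``quantile`` of off-diagonal scores, or
    an ``absolute`` score).  Isolated nodes are retained.  Edge weights hold
    the similarity score; node attributes carry phylum and median stand
    abundance when provided.
    """
    threshold = _resolve_threshold(sim.scores, quantile, absolute)
    g = nx.Graph(
        stage=stage,
        threshold=threshold,
        threshold_rule="absolute" if absolute is not None else f"quantile={quantile}",
        d_max=sim.d_max,
        score_cap=sim.cap,
    )
    for i, otu in enumerate(sim.ids):
        attrs = {}
        if node_phylum is not None:
            attrs["phylum"] = node_phylum.get(otu, "unclassified")
        if node_abundance is not None:
            attrs["median_abundance"] = float(node_abundance[otu])
        g.add_node(otu, **attrs)
    n = len(sim.ids)
    iu = np.triu_indices(n, k=1)
    keep = sim.scores[iu] >= threshold
    for i, j in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(sim.ids[i], sim.ids[j], weight=float(sim.scores[i, j]))
    if g.number_of_edges() == 0:
        warnings.warn("threshold excludes all pairs; network has no edges")
    return g


def node_attributes_from_profile(
    profile: AbundanceProfile,
) -> tuple[dict[str, str], dict[str, float]]:
    """Phylum and median stand abundance per OTU for node annotation."""
    phyla: dict[str, str] = {}
    if profile.lineages is not None:
        for otu, lin in profile.lineages.items():
            phyla[otu] = parse_lineage(lin).get("phylum", "unclassified")
    medians = profile.values.median(axis=1).to_dict()
    return phyla, {k: float(v) for k, v in medians.items()}


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    average_path_length: float | None
    diameter: int | None
    modularity: float
    n_components: int


def _modularity(g: nx.Graph, communities) -> float:
    """Q = sum_c [L_c/m - (d_c/2m)^2] with a deterministic summation order
    (communities sorted by smallest member), so results are reproducible
    to the last bit across processes."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in sorted(communities, key=lambda c: min(str(v) for v in c)):
        sub = g.subgraph(comm)
        l_c = sub.number_of_edges()
        d_c = sum(d for _, d in g.degree(sorted(comm, key=str)))
        q += l_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def topology(g: nx.Graph) -> NetworkTopology:
    """Summary topology: mean local CC, APL over connected pairs, diameter
    of the largest component, and CNM greedy modularity."""
    if g.number_of_nodes() < 1:
        raise ValueError("network has no nodes")
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    cc = float(np.mean(list(nx.clustering(g).values())))
    components = sorted(
        nx.connected_components(g), key=lambda c: (-len(c), min(c))
    )
    apl: float | None = None
    diameter: int | None = None
    if n_edges > 0:
        total_len = 0
        total_pairs = 0
        for comp in components:
            if len(comp) < 2:
                continue
            sub = g.subgraph(comp)
            for _, lengths in nx.all_pairs_shortest_path_length(sub):
                total_len += sum(lengths.values())
            total_pairs += len(comp) * (len(comp) - 1)
        apl = total_len / total_pairs
        diameter = int(nx.diameter(g.subgraph(components[0])))
        communities = nx.community.greedy_modularity_communities(g)
        q = _modularity(g, communities)
    else:
        q = 0.0
    return NetworkTopology(
        n_nodes=n_nodes,
        n_edges=n_edges,
        clustering_coefficient=cc,
        average_path_length=apl,
        diameter=diameter,
        modularity=q,
        n_components=len(components),
    )


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------


@dataclass
class NullModelResult:
    observed_edges: int
    null_edge_counts: np.ndarray
    expected_edges: float
    chi_square: float
    p_chi: float
    p_empirical: float
    threshold: float
    n_iterations: int
    seed: int | None


def _chi_square_one_cell(observed: float, expected: float) -> tuple[float, float]:
    if expected <= 0:
        return float("nan"), float("nan")
    chi = (observed - expected) ** 2 / expected
    return float(chi), float(ss.chi2.sf(chi, df=1))


def _empirical_two_sided(observed: int, null_counts: np.ndarray) -> float:
    b = len(null_counts)
    upper = (1 + int((null_counts >= observed).sum())) / (1 + b)
    lower = (1 + int((null_counts <= observed).sum())) / (1 + b)
    return float(min(1.0, 2.0 * min(upper, lower)))


def _permute_rows(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently shuffle each row across columns (multiset-preserving)."""
    keys = rng.random(values.shape)
    order = np.argsort(keys, axis=1)
    return np.take_along_axis(values, order, axis=1)


def null_edge_distribution(
    profile: AbundanceProfile,
    quantile: float | None = 0.9,
    absolute: float | None = None,
    n_iterations: int = 1000,
    seed: int | None = None,
) -> NullModelResult:
    """Edge-count null distribution under per-OTU abundance permutation.

    Each iteration shuffles every OTU's abundance vector across the stand's
    samples, recomputes the log-score similarities (with that iteration's
    own d_max and cap) and counts edges at an ABSOLUTE threshold frozen from
    the observed network.  Reports the null mean as the expected edge count,
    the one-cell chi-square (O-E)^2/E with df=1, and a two-sided empirical
    p-value from the null draws (preferred: it makes no distributional
    assumption).
    """
    if n_iterations < 100:
        warnings.warn(
            f"n_iterations={n_iterations} < 100: expected edge count unstable"
        )
    values = profile.values.to_numpy()
    scores, _, _, _ = _scores_from_values(values)
    threshold = _resolve_threshold(scores, quantile, absolute)
    iu = np.triu_indices(scores.shape[0], k=1)
    observed = int((scores[iu] >= threshold).sum())

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_iterations, dtype=np.int64)
    for b in range(n_iterations):
        permuted = _permute_rows(values, rng)
        scores_b, _, _, _ = _scores_from_values(permuted)
        null_counts[b] = int((scores_b[iu] >= threshold).sum())

    expected = float(null_counts.mean())
    chi, p_chi = _chi_square_one_cell(observed, expected)
    p_emp = _empirical_two_sided(observed, null_counts)
    return NullModelResult(
        observed_edges=observed,
        null_edge_counts=null_counts,
        expected_edges=expected,
        chi_square=chi,
        p_chi=p_chi,
        p_empirical=p_emp,
        threshold=threshold,
        n_iterations=n_iterations,
        seed=seed,
    )


def erdos_renyi_null(
    n_nodes: int, n_edges_mean: float, n_iterations: int = 1000,
    seed: int | None = None,
) -> list[nx.Graph]:
    """G(n, m) random graphs with the observed node count — the alternative
    null for topology comparisons (fixed expected edge count)."""
    rng = np.random.default_rng(seed)
    m = int(round(n_edges_mean))
    return [
        nx.gnm_random_graph(n_nodes, m, seed=int(rng.integers(2**31)))
        for _ in range(n_iterations)
    ]


# ---------------------------------------------------------------------------
# keystones
# ---------------------------------------------------------------------------


@dataclass
class KeystoneReport:
    table: pd.DataFrame  # otu_id, betweenness, percentile, keystone, tie_at_cut
    cutoff: float
    n_keystones: int
    boundary_tie: bool


def keystones(g: nx.Graph) -> KeystoneReport:
    """Flag OTUs in the top decile of normalized betweenness centrality.

    The keystone count is ceil(0.10 * n_nodes); ties at the cutoff are all
    included and annotated.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("need at least two nodes")
    bc = nx.betweenness_centrality(g, normalized=True)
    ids = sorted(g.nodes)
    values = np.array([bc[i] for i in ids])
    k = math.ceil(0.10 * len(ids))
    order = sorted(range(len(ids)), key=lambda i: (-values[i], ids[i]))
    cutoff = values[order[k - 1]]
    flag = values >= cutoff - 1e-15
    n_flagged = int(flag.sum())
    tie = n_flagged > k
    percentile = ss.rankdata(values) / len(values) * 100.0
    table = pd.DataFrame(
        {
            "otu_id": ids,
            "betweenness": values,
            "percentile": percentile,
            "keystone": flag,
            "tie_at_cut": flag & np.isclose(values, cutoff) if tie else False,
        }
    )
    if "phylum" in next(iter(g.nodes(data=True)))[1]:
        table["phylum"] = [g.nodes[i].get("phylum", "unclassified") for i in ids]
    table = table.sort_values(
        ["betweenness", "otu_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return KeystoneReport(
        table=table, cutoff=float(cutoff), n_keystones=n_flagged, boundary_tie=tie
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_graphml(g: nx.Graph, path) -> None:
    out = g.copy()
    for key in ("stage",):
        if out.graph.get(key) is None:
            out.graph.pop(key, None)
    nx.write_graphml(out, path)


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "similarity": d.get("weight", np.nan)}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "similarity"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_table(g: nx.Graph, report: KeystoneReport, path) -> None:
    frame = report.table.copy()
    if "phylum" not in frame.columns:
        frame["phylum"] = "unclassified"
    frame["median_abundance"] = [
        g.nodes[o].get("median_abundance", np.nan) for o in frame["otu_id"]
    ]
    frame.to_csv(path, sep="\t", index=False)
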