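"""Group-comparison and association statistics for community profiles.

Implements the comparison toolkit used on the chronosequence communities:
Bray-Curtis dissimilarity, one-way ANOSIM with a permutation (or exact
enumeration) p-value, SIMPER decomposition of between-group dissimilarity,
Spearman correlation matrices with exact small-n p-values, ordinary linear
fits, and the row-normalized complete-linkage clustering behind the
heat-map display.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io_tables import AbundanceProfile

EXACT_ENUMERATION_LIMIT = 10_000


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(profile: AbundanceProfile) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    values = profile.values.to_numpy().T  # samples x taxa
    if values.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero = profile.values.columns[values.sum(axis=1) == 0].tolist()
    if len(zero) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined for all-zero sample pairs: {zero}"
        )
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(profile.values.columns))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    method: str  # "exact" or "permutation"
    group_sizes: dict[str, int]


def _distinct_arrangement_count(sizes: list[int]) -> int:
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def _distinct_label_arrangements(codes: np.ndarray) -> np.ndarray:
    """All distinct assignments of the multiset of group codes to positions."""
    n = len(codes)
    groups, counts = np.unique(codes, return_counts=True)
    arrangements: list[np.ndarray] = []

    def recurse(positions: tuple[int, ...], gi: int, current: np.ndarray) -> None:
        if gi == len(groups) - 1:
            filled = current.copy()
            filled[list(positions)] = groups[gi]
            arrangements.append(filled)
            return
        for chosen in itertools.combinations(positions, counts[gi]):
            nxt = current.copy()
            nxt[list(chosen)] = groups[gi]
            remaining = tuple(p for p in positions if p not in set(chosen))
            recurse(remaining, gi + 1, nxt)

    recurse(tuple(range(n)), 0, np.full(n, -1, dtype=np.int64))
    return np.stack(arrangements)


def _anosim_r_from_ranks(rank_matrix: np.ndarray, codes: np.ndarray) -> float:
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    within = codes[iu[0]] == codes[iu[1]]
    r_within = rank_matrix[iu][within].mean()
    r_between = rank_matrix[iu][~within].mean()
    return float((r_between - r_within) / (n * (n - 1) / 4.0))


def anosim(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> AnosimResult:
    """One-way analysis of similarity on a dissimilarity matrix.

    ``groups`` maps sample id -> group label (mapping or aligned sequence).
    Ties among dissimilarities get midranks.  R compares mean between- and
    within-group ranks scaled by n(n-1)/4.  When the number of distinct
    label arrangements is small (<= 10,000) the p-value is computed by
    exact enumeration (the observed arrangement counts itself); otherwise
    by uniform random label permutations with the add-one estimator
    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations).
    """
    ids = list(dist.ids)
    if isinstance(groups, dict):
        labels = [groups[i] for i in ids]
    else:
        labels = list(groups)
        if len(labels) != len(ids):
            raise ValueError("groups length must match distance matrix")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    sizes = {g: labels.count(g) for g in uniq}
    if min(sizes.values()) < 2:
        small = [g for g, s in sizes.items() if s < 2]
        raise ValueError(f"groups with fewer than two samples: {small}")
    codes = np.array([uniq.index(g) for g in labels], dtype=np.int64)

    n = len(ids)
    condensed = squareform(np.asarray(dist.data), checks=False)
    ranks = ss.rankdata(condensed)  # midranks
    rank_matrix = squareform(ranks, checks=False)

    r_obs = _anosim_r_from_ranks(rank_matrix, codes)

    n_arrangements = _distinct_arrangement_count(sorted(sizes.values()))
    iu = np.triu_indices(n, k=1)
    pair_ranks = rank_matrix[iu]
    denom = n * (n - 1) / 4.0

    def r_for(all_codes: np.ndarray) -> np.ndarray:
        # all_codes: (m, n) -> vector of R statistics
        within = all_codes[:, iu[0]] == all_codes[:, iu[1]]
        w_sum = within @ pair_ranks
        w_cnt = within.sum(axis=1)
        total = pair_ranks.sum()
        b_sum = total - w_sum
        b_cnt = len(pair_ranks) - w_cnt
        return (b_sum / b_cnt - w_sum / w_cnt) / denom

    if n_arrangements <= EXACT_ENUMERATION_LIMIT:
        arrangements = _distinct_label_arrangements(codes)
        r_all = r_for(arrangements)
        p = float((r_all >= r_obs).sum() / len(r_all))
        return AnosimResult(
            r=r_obs, p=p, n_permutations=len(r_all), seed=seed,
            method="exact", group_sizes=sizes,
        )

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(codes) for _ in range(n_permutations)])
    r_perm = r_for(perms)
    p = float((1 + (r_perm >= r_obs).sum()) / (1 + n_permutations))
    return AnosimResult(
        r=r_obs, p=p, n_permutations=n_permutations, seed=seed,
        method="permutation", group_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


@dataclass
class SimperResult:
    contributions: pd.DataFrame  # taxon, mean_contribution, percent, cumulative
    overall_dissimilarity: float
    group_a: str
    group_b: str


def simper(profile: AbundanceProfile, groups, pair=None) -> SimperResult:
    """Per-taxon contributions to mean between-group Bray-Curtis.

    For every between-group sample pair (j, k), taxon i contributes
    |x_ij - x_ik| / sum_m (x_mj + x_mk); contributions are averaged over all
    between pairs and sum exactly to the mean between-group Bray-Curtis.
    ``pair`` selects the two group labels when more than two are present.
    """
    ids = list(profile.values.columns)
    if isinstance(groups, dict):
        labels = [groups[i] for i in ids]
    else:
        labels = list(groups)
        if len(labels) != len(ids):
            raise ValueError("groups length must match profile samples")
    uniq = sorted(set(labels))
    if pair is None:
        if len(uniq) != 2:
            raise ValueError(
                f"profile has groups {uniq}; pass pair=(a, b) to select two"
            )
        pair = (uniq[0], uniq[1])
    a, b = pair
    idx_a = [j for j, lab in enumerate(labels) if lab == a]
    idx_b = [j for j, lab in enumerate(labels) if lab == b]
    if not idx_a or not idx_b:
        raise ValueError(f"empty group in pair {pair}")

    x = profile.values.to_numpy()  # taxa x samples
    taxa = list(profile.values.index)
    contrib = np.zeros(len(taxa))
    n_pairs = 0
    for j in idx_a:
        for k in idx_b:
            denom = (x[:, j] + x[:, k]).sum()
            if denom == 0:
                raise ValueError(
                    f"samples {ids[j]!r} and {ids[k]!r} have zero combined "
                    "abundance"
                )
            contrib += np.abs(x[:, j] - x[:, k]) / denom
            n_pairs += 1
    contrib /= n_pairs
    overall = float(contrib.sum())

    order = sorted(
        range(len(taxa)), key=lambda i: (-contrib[i], taxa[i])
    )
    sorted_contrib = contrib[order]
    percent = (
        100.0 * sorted_contrib / overall
        if overall > 0
        else np.zeros_like(sorted_contrib)
    )
    frame = pd.DataFrame(
        {
            "taxon": [taxa[i] for i in order],
            "mean_contribution": sorted_contrib,
            "percent": percent,
            "cumulative_percent": np.cumsum(percent),
        }
    )
    return SimperResult(
        contributions=frame, overall_dissimilarity=overall, group_a=a, group_b=b
    )


# ---------------------------------------------------------------------------
# Spearman matrices
# ---------------------------------------------------------------------------


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of one rank vector."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    zx = (rx - rx.mean()) / rx.std()
    ry_c = ry - ry.mean()
    sy = ry.std()
    rho_perm = (ry_c[perms] @ zx) / (n * sy)
    return float((np.abs(rho_perm) >= abs(rho_obs) - 1e-12).mean())


def spearman_matrix(
    x: pd.DataFrame, y: pd.DataFrame, exact_max_n: int = 8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every (row of x, row of y) variable pair.

    Rows are variables, columns are shared samples.  Midranks handle ties.
    With n <= ``exact_max_n`` paired observations the two-sided p-value is
    exact (full permutation enumeration), matching the small-n regime of a
    nine-sample chronosequence; otherwise the t approximation is used.
    Constant variables yield missing entries with a warning.
    """
    common = [c for c in x.columns if c in y.columns]
    if len(common) < 4:
        raise ValueError("need at least 4 paired observations")
    xv = x.loc[:, common]
    yv = y.loc[:, common]
    n = len(common)
    rho = pd.DataFrame(np.nan, index=x.index, columns=y.index)
    pval = pd.DataFrame(np.nan, index=x.index, columns=y.index)
    for xi in x.index:
        a = xv.loc[xi].to_numpy(dtype=float)
        if np.all(a == a[0]):
            warnings.warn(f"variable {xi!r} is constant; rho undefined")
            continue
        ra = ss.rankdata(a)
        for yi in y.index:
            b = yv.loc[yi].to_numpy(dtype=float)
            if np.all(b == b[0]):
                warnings.warn(f"variable {yi!r} is constant; rho undefined")
                continue
            res = ss.spearmanr(a, b)
            rho.loc[xi, yi] = res.statistic
            if n <= exact_max_n:
                rb = ss.rankdata(b)
                pval.loc[xi, yi] = _exact_spearman_p(ra, rb, res.statistic)
            else:
                pval.loc[xi, yi] = res.pvalue
    return rho, pval


# ---------------------------------------------------------------------------
# linear fit
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p: float


def linear_fit_r2(x, y) -> LinearFit:
    """Ordinary least squares y ~ x with r-squared and F-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.all(x == x[0]):
        raise ValueError("x is constant; fit undefined")
    res = ss.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# heat-map normalization + complete-linkage clustering
# ---------------------------------------------------------------------------


@dataclass
class HeatmapResult:
    matrix: pd.DataFrame  # row z-scores, rows/cols in clustered order
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None


def _deterministic_leaf_order(linkage: np.ndarray, labels: list[str]) -> list[int]:
    """Leaf order with the smaller-min-label subtree on the left."""
    n = len(labels)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        lv, rv = leaves(left), leaves(right)
        if min(labels[i] for i in rv) < min(labels[i] for i in lv):
            lv, rv = rv, lv
        return lv + rv

    return leaves(2 * n - 2) if n > 1 else [0]


def heatmap_matrix(
    profile: AbundanceProfile, cluster_columns: bool = True
) -> HeatmapResult:
    """Row z-scores with complete-linkage Euclidean clustering of both axes.

    Rows with zero variance normalize to all-zero.  Leaf ordering is
    deterministic (left subtree holds the lexicographically smallest id).
    """
    values = profile.values
    if values.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    mat = values.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    # rows constant up to floating error normalize to zero
    tol = 1e-12 * max(1.0, float(np.abs(mat).max()))
    varying = sd > tol
    normed = np.where(varying, (mat - mean) / np.where(varying, sd, 1.0), 0.0)

    row_labels = list(values.index)
    row_linkage = sch.linkage(normed, method="complete", metric="euclidean")
    row_idx = _deterministic_leaf_order(row_linkage, row_labels)
    row_order = [row_labels[i] for i in row_idx]

    col_labels = list(values.columns)
    col_linkage = None
    col_order = col_labels
    if cluster_columns and len(col_labels) > 2:
        col_linkage = sch.linkage(normed.T, method="complete", metric="euclidean")
        col_idx = _deterministic_leaf_order(col_linkage, col_labels)
        col_order = [col_labels[i] for i in col_idx]

    frame = pd.DataFrame(normed, index=row_labels, columns=col_labels)
    frame = frame.loc[row_order, col_order]
    return HeatmapResult(
        matrix=frame,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as Newick; branch lengths are height gaps."""
    n = len(labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(linkage[node - n, 2])

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - height(node)
        if node < n:
            return f"{labels[node]}:{bl:.10g}"
        left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = 2 * n - 2
    h = height(root)
    left, right = int(linkage[root - n, 0]), int(linkage[root - n, 1])
    return f"({render(left, h)},{render(right, h)});"
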