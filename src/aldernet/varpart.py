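"""Redundancy analysis and variance partitioning.

RDA regresses a (multivariate) community response on an explanatory matrix
and eigen-decomposes the fitted values; the explained proportion is the
fitted sum of squares over the total.  Variance partitioning splits the
adjusted R-squared (Ezekiel correction) of up to four explanatory sets into
disjoint unique and shared components over the subset lattice, as in
partial-ordination variance decomposition.  Components of adjusted R^2 can
legitimately be negative and are reported as-is.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def hellinger(y: np.ndarray) -> np.ndarray:
    """Hellinger transform of a samples x taxa abundance matrix."""
    y = np.asarray(y, dtype=float)
    totals = y.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("every sample needs positive total abundance")
    return np.sqrt(y / totals)


@dataclass
class RdaResult:
    eigenvalues: np.ndarray  # constrained axes, non-increasing
    proportion_explained: np.ndarray  # per axis, of total variance
    total_explained: float
    species_scores: np.ndarray
    site_scores: np.ndarray
    rank_deficient: bool


def rda(y, x, transform: str | None = None) -> RdaResult:
    """Redundancy analysis of response ``y`` (samples x taxa) on ``x``.

    ``transform='hellinger'`` square-root-transforms compositional rows
    first (recommended for OTU-level responses).  Both matrices are column
    centred; the fit uses a pseudo-inverse, so collinear predictors degrade
    gracefully (with a warning).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("y and x need the same number of samples (rows)")
    if n < x.shape[1] + 2:
        raise ValueError(
            f"need samples >= predictors + 2 ({n} samples, {x.shape[1]} predictors)"
        )
    if transform == "hellinger":
        y = hellinger(y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc) if xc.size else 0
    deficient = rank < xc.shape[1]
    if deficient:
        warnings.warn(
            f"explanatory matrix is rank deficient (rank {rank} < "
            f"{xc.shape[1]} columns); using pseudo-inverse"
        )
    beta = np.linalg.pinv(xc) @ yc
    yhat = xc @ beta
    total_ss = float((yc**2).sum())
    if total_ss == 0:
        raise ValueError("response has zero variance")
    u, s, vt = np.linalg.svd(yhat / np.sqrt(max(n - 1, 1)), full_matrices=False)
    eigenvalues = s**2
    keep = eigenvalues > 1e-12 * max(eigenvalues.max(initial=0.0), 1e-300)
    eigenvalues = eigenvalues[keep]
    proportions = eigenvalues * (n - 1) / total_ss
    return RdaResult(
        eigenvalues=eigenvalues,
        proportion_explained=proportions,
        total_explained=float((yhat**2).sum() / total_ss),
        species_scores=vt[keep].T,
        site_scores=u[:, keep] * s[keep],
        rank_deficient=deficient,
    )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel-corrected R^2; NaN (undefined) when n <= p + 1."""
    if n <= p + 1:
        warnings.warn(f"adjusted R^2 undefined for n={n}, p={p}")
        return float("nan")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass
class VarpartResult:
    set_names: list[str]
    components: dict[frozenset[str], float]  # disjoint Venn components
    unique: dict[str, float]
    subset_adj_r2: dict[frozenset[str], float]  # adjR^2 of every subset union
    total_explained: float
    residual: float

    def component_table(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.components, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {
                    "component": "&".join(sorted(key)),
                    "adj_r2": self.components[key],
                }
            )
        rows.append({"component": "residual", "adj_r2": self.residual})
        return pd.DataFrame(rows)


def variance_partition(
    y,
    x_sets: dict[str, np.ndarray],
    transform: str | None = None,
) -> VarpartResult:
    """Partition adjusted R^2 of ``y`` among 2-4 explanatory matrices.

    For every non-empty subset S of sets, the adjusted R^2 of the union is
    computed via RDA (OLS when y is univariate).  Disjoint Venn components
    c(A) then solve f(S) = sum over {A : A intersects S} c(A), so the
    components sum to the full-model adjusted R^2 by construction.  The
    unique fraction of set i equals f(all) - f(all minus i).
    """
    names = list(x_sets)
    k = len(names)
    if not 2 <= k <= 4:
        raise ValueError("variance_partition expects 2-4 explanatory sets")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    mats = {}
    for name in names:
        m = np.asarray(x_sets[name], dtype=float)
        if m.ndim == 1:
            m = m[:, None]
        if m.shape[0] != n:
            raise ValueError(f"set {name!r} has {m.shape[0]} rows, expected {n}")
        mc = m - m.mean(axis=0)
        if np.linalg.matrix_rank(mc) < mc.shape[1]:
            raise ValueError(f"set {name!r} is not full column rank after centering")
        mats[name] = m
    p_total = sum(m.shape[1] for m in mats.values())
    if p_total >= n - 1:
        raise ValueError(
            f"{p_total} combined predictors with {n} samples; reduce variables "
            "(need combined predictors < n - 1)"
        )

    subsets = []
    for r in range(1, k + 1):
        subsets.extend(frozenset(c) for c in itertools.combinations(names, r))

    f: dict[frozenset[str], float] = {}
    for s in subsets:
        x = np.hstack([mats[name] for name in names if name in s])
        res = rda(y, x, transform=transform)
        # penalize by effective degrees of freedom (rank), so collinear
        # unions of sets are not over-penalized
        p_eff = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
        f[s] = adjusted_r2(res.total_explained, n, p_eff)

    # solve M c = f with M[S, A] = 1 iff A and S intersect
    m_mat = np.array(
        [[1.0 if a & s else 0.0 for a in subsets] for s in subsets]
    )
    fvec = np.array([f[s] for s in subsets])
    cvec = np.linalg.solve(m_mat, fvec)
    components = {a: float(c) for a, c in zip(subsets, cvec)}

    full = frozenset(names)
    unique = {
        name: f[full] - (f[full - {name}] if k > 1 else 0.0) for name in names
    }
    return VarpartResult(
        set_names=names,
        components=components,
        unique=unique,
        subset_adj_r2=f,
        total_explained=f[full],
        residual=float(1.0 - f[full]),
    )


def encode_stage(stages, one_hot: bool = False) -> np.ndarray:
    """Chronosequence stage coding: ordinal 0/1/2 (default) or one-hot."""
    order = {"juvenile": 0, "young": 1, "mature": 2}
    codes = np.array([order[s] for s in stages], dtype=float)
    if not one_hot:
        return codes[:, None]
    out = np.zeros((len(codes), 2))
    for i, c in enumerate(codes.astype(int)):
        if c >= 1:
            out[i, c - 1] = 1.0
    return out


def encode_depth(depth_bands) -> np.ndarray:
    """Ordinal coding of the three sampling depth bands."""
    order = {"0-10": 0, "10-20": 1, "20-30": 2}
    return np.array([order[d] for d in depth_bands], dtype=float)[:, None]
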