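"""Alpha diversity: Shannon index, observed richness, exact rarefaction.

Rarefaction uses Hurlbert's closed-form expectation of the number of taxa
seen in a random subsample without replacement,

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ],

computed with log-gamma arithmetic so large library sizes do not overflow.
The analytic form is preferred over resampling for determinism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_tables import OtuTable

_LOG_BASES = {"e": 1.0, 2: np.log(2.0), "2": np.log(2.0)}


def shannon(counts, base="e") -> float:
    """Shannon entropy H = -sum p_i log(p_i) of a count vector."""
    if base not in _LOG_BASES:
        raise ValueError(f"base must be 'e' or 2, got {base!r}")
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / _LOG_BASES[base])


def richness(counts) -> int:
    """Number of taxa with a strictly positive count."""
    c = np.asarray(counts, dtype=float)
    return int((c > 0).sum())


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness E[S_n] at each subsample size in ``depths``."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    total = c.sum()
    depths = np.asarray(depths)
    if (depths < 1).any():
        raise ValueError("subsample sizes must be >= 1")
    if (depths > total).any():
        raise ValueError(
            f"subsample size exceeds total count {int(total)}: "
            f"{depths[depths > total].tolist()}"
        )
    out = np.empty(len(depths), dtype=float)
    for j, n in enumerate(depths):
        n = float(n)
        # log C(N - N_i, n) - log C(N, n); zero probability when N - N_i < n
        feasible = total - c >= n
        log_num = gammaln(total - c[feasible] + 1) - gammaln(
            total - c[feasible] - n + 1
        )
        log_den = gammaln(total + 1) - gammaln(total - n + 1)
        prob_unseen = np.exp(log_num - log_den)
        out[j] = (1.0 - prob_unseen).sum() + (~feasible).sum() * 1.0
    return out


def diversity_table(table: OtuTable, base="e") -> pd.DataFrame:
    """Per-sample richness and Shannon index (long TSV-ready frame)."""
    rows = []
    for sid in table.sample_ids:
        c = table.counts[sid].to_numpy()
        rows.append(
            {
                "sample_id": sid,
                "richness": richness(c),
                "shannon": shannon(c, base=base),
                "base": str(base),
            }
        )
    return pd.DataFrame(rows)


def rarefaction_table(table: OtuTable, n_points: int = 10) -> pd.DataFrame:
    """Rarefaction curves for every sample at evenly spaced depths."""
    rows = []
    for sid in table.sample_ids:
        c = table.counts[sid].to_numpy()
        total = int(c.sum())
        depths = np.unique(np.linspace(1, total, n_points, dtype=np.int64))
        expected = rarefaction_curve(c, depths)
        for d, e in zip(depths, expected):
            rows.append(
                {"sample_id": sid, "depth": int(d), "expected_richness": float(e)}
            )
    return pd.DataFrame(rows)
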