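"""Shared statistical primitives: BH-FDR and the Wilcoxon rank-sum test.

The rank-sum test switches between exact enumeration (both group sizes at
most ``EXACT_MAX_N``) and the normal approximation with tie and continuity
correction.  Exact p-values use midranks, so ties are handled correctly at
small n as well.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import InputError

EXACT_MAX_N = 8


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Values must lie in (0, 1].  The output is monotone in the input order
    statistics, capped at 1, and returned in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Enumerates every assignment of the combined midranks to the first group
    and reports P(|W - E[W]| >= |w_obs - E[W]|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n1 = x.size
    n = combined.size
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    crit = abs(w_obs - mean_w) - 1e-12
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mean_w) >= crit:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(x, y) -> float:
    """Two-sided rank-sum p-value; exact for small groups, asymptotic otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        return exact_rank_sum_p(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def rank_sum_test_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values for two cell-by-gene blocks."""
    if x.shape[0] <= EXACT_MAX_N and y.shape[0] <= EXACT_MAX_N:
        return np.array(
            [exact_rank_sum_p(x[:, j], y[:, j]) for j in range(x.shape[1])]
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=0)
    return np.asarray(res.pvalue, dtype=float)
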