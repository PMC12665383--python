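"""Independent brute-force oracles used by the validation tests.

These deliberately avoid the package's own implementations: the BH oracle
evaluates the step-up definition literally, and the rank-sum oracle
enumerates group assignments of the raw values, recomputing midranks for
every assignment.
"""

from itertools import combinations

import numpy as np


def bh_stepup_bruteforce(pvals):
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    for i in range(n):
        adj[order[i]] = min(
            min(n * p[order[j]] / (j + 1) for j in range(i, n)), 1.0)
    return adj


def _rank_sum_of(values, idx):
    """Sum of midranks of the selected positions."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks[list(idx)].sum()


def ranksum_bruteforce(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    n, n1 = combined.size, x.size
    w_obs = _rank_sum_of(combined, range(n1))
    mean_w = n1 * (n + 1) / 2.0
    crit = abs(w_obs - mean_w) - 1e-12
    hits = total = 0
    for idx in combinations(range(n), n1):
        if abs(_rank_sum_of(combined, idx) - mean_w) >= crit:
            hits += 1
        total += 1
    return hits / total
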