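"""Independent brute-force oracles used by the test-suite.

Each oracle recomputes a quantity by exhaustive enumeration or direct
summation, fully independently of the package's implementation path.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_matching_cost(cost: np.ndarray, allowed: np.ndarray, alt: float) -> float:
    """Minimum of sum(link costs) + alt * (#unmatched) over all partial matchings."""
    n, m = cost.shape

    def rec(i, used_cols):
        if i == n:
            return alt * (m - len(used_cols))
        best = alt + rec(i + 1, used_cols)  # leave row i unmatched
        for j in range(m):
            if j not in used_cols and allowed[i, j]:
                best = min(best, cost[i, j] + rec(i + 1, used_cols | {j}))
        return best

    return rec(0, frozenset())


def wls_slope_direct(t: np.ndarray, x: np.ndarray, w: np.ndarray) -> float:
    """Weighted least-squares slope by direct summation of the normal equations."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    tbar = np.sum(w * t) / np.sum(w)
    return float(np.sum(w * (t - tbar) * x) / np.sum(w * (t - tbar) ** 2))


def signed_rank_p_enumeration(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for bits in range(2**n):
        signs = np.array([(bits >> k) & 1 for k in range(n)])
        ws.append(ranks[signs == 1].sum())
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney_p_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2

    us = []
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    mean_u = n1 * len(b) / 2
    # two-sided by symmetry of U around its mean
    dev = abs(u_obs - mean_u)
    return float(np.mean(np.abs(us - mean_u) >= dev - 1e-12))
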