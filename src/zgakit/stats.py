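"""Rank statistics shared across the analyses.

The Wilcoxon / Mann-Whitney rank-sum test is implemented once here with a
testable dialect: exact enumeration of the permutation distribution when
the smaller group has at most ``EXACT_MAX`` observations (ties handled by
permuting the observed midranks), and the tie-corrected normal
approximation otherwise.  Benjamini-Hochberg adjustment follows the
step-up definition with the running-minimum enforcement of monotonicity.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

EXACT_MAX = 10
# cap on the enumeration size so a tiny group paired with a huge one
# cannot trigger a combinatorial explosion
_EXACT_MAX_COMBOS = 500_000


def rank_sum_test(x, y, exact_max: int = EXACT_MAX) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where U counts pairs ``(x_i, y_j)`` with
    ``x_i > y_j`` plus half the ties (the statistic for the first sample).

    For ``min(len(x), len(y)) <= exact_max`` the p-value is computed by
    exhaustive enumeration over all ``C(n+m, n)`` assignments of the
    pooled ranks, which is correct under ties as a permutation test.
    Larger samples use the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0

    if min(n, m) <= exact_max and comb(n + m, min(n, m)) <= _EXACT_MAX_COMBOS:
        # |U_x - nm/2| == |U_y - nm/2|, so enumerating the smaller group
        # yields the same two-sided p
        p = _exact_two_sided_p(ranks, min(n, m), abs(u_x - n * m / 2.0))
        return float(u_x), float(p)

    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    total = n + m
    var = n * m / 12.0 * (total + 1 - tie_term / (total * (total - 1)))
    if var == 0:
        return float(u_x), 1.0
    z = (abs(u_x - mu) - 0.5) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return float(u_x), float(min(p, 1.0))


def _exact_two_sided_p(ranks: np.ndarray, k: int, dev_obs: float) -> float:
    """Permutation p-value: enumerate every choice of ``k`` pooled ranks."""
    total = len(ranks)
    offset = k * (k + 1) / 2.0
    mu = k * (total - k) / 2.0
    dev_obs -= 1e-12
    count = hits = 0
    for combo in combinations(range(total), k):
        u = ranks[list(combo)].sum() - offset
        count += 1
        if abs(u - mu) >= dev_obs:
            hits += 1
    return hits / count


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman(x, y) -> float:
    """Spearman rank correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)
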