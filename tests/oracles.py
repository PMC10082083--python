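"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exact integer
arithmetic for the Fisher test, the literal min-over-tail definition for
BH, and full enumeration of group assignments for the rank-sum test.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_exact(m1: int, u1: int, m2: int, u2: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration.

    Table probabilities are compared as exact integers (the shared
    denominator cancels), so ties are handled without any tolerance.
    """
    n1, n2 = m1 + u1, m2 + u2
    K = m1 + m2
    lo, hi = max(0, K - n2), min(K, n1)
    weights = [comb(n1, k) * comb(n2, K - k) for k in range(lo, hi + 1)]
    w_obs = weights[m1 - lo]
    total = sum(weights)
    if total == 0:
        return 1.0
    return sum(w for w in weights if w <= w_obs) / total


def fisher_group_pvalues(n1: int, n2: int, K: int) -> np.ndarray:
    """Two-sided Fisher p for every observed cell of a fixed-margin family.

    Returns p for each m1 in the support of (n1, n2, K), computed with the
    same exact-integer tie rule as :func:`fisher_two_sided_exact`.
    """
    lo, hi = max(0, K - n2), min(K, n1)
    weights = [comb(n1, k) * comb(n2, K - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    order = sorted(range(len(weights)), key=weights.__getitem__)
    sorted_w = [weights[i] for i in order]
    prefix = np.cumsum([float(w) for w in sorted_w])
    out = np.empty(len(weights))
    import bisect
    for i, w in enumerate(weights):
        pos = bisect.bisect_right(sorted_w, w)
        out[i] = prefix[pos - 1] / total
    return out


def bh_min_over_tail(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p by the literal definition:
    p_adj(i) = min over {j: p_j >= p_i} of min(1, p_j * n / rank_j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    out = np.empty(n)
    for pos in range(n):
        tail = [min(1.0, ranked[j] * n / (j + 1)) for j in range(pos, n)]
        out[order[pos]] = min(tail)
    return out


def mannwhitney_exact_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments
    (no-ties case): 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)

    def u_of(rank_sum):
        return rank_sum - n1 * (n1 + 1) / 2

    u_obs = u_of(sum(ranks[v] for v in x))
    us = [u_of(sum(c)) for c in combinations(range(1, n1 + n2 + 1), n1)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
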