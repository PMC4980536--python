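"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming code paths:
local alignment scores are recomputed by exhaustive enumeration over
substring pairs with a plain-recursion global aligner, and the lambda
root is recomputed by bisection on a fixed grid.
"""

from __future__ import annotations

from functools import lru_cache
from math import exp


def brute_force_local_score(a: str, b: str, pair_scores, gap_open: float,
                            gap_extend: float) -> float:
    """Maximum local alignment score by enumeration over substring pairs.

    The best local alignment of ``a`` and ``b`` is the best global
    alignment over all pairs of substrings (terminal gaps only lower a
    global score, so trimmed substrings dominate), or the empty alignment
    of score 0.  A gap of length L costs ``gap_open + L * gap_extend``;
    adjacent gaps in opposite sequences each pay their own opening cost.
    """
    open_cost = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def global_best(sa: str, sb: str, i: int, j: int, prev: str) -> float:
        if i == len(sa) and j == len(sb):
            return 0.0
        best = float("-inf")
        if i < len(sa) and j < len(sb):
            best = pair_scores[(sa[i], sb[j])] + global_best(sa, sb, i + 1, j + 1, "M")
        if i < len(sa):
            cost = gap_extend if prev == "X" else open_cost
            best = max(best, -cost + global_best(sa, sb, i + 1, j, "X"))
        if j < len(sb):
            cost = gap_extend if prev == "Y" else open_cost
            best = max(best, -cost + global_best(sa, sb, i, j + 1, "Y"))
        return best

    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_best(a[i1:i2], b[j1:j2], 0, 0, "M")
                    if s > best:
                        best = s
    global_best.cache_clear()
    return best


def bisect_lambda(score_dist: dict[int, float], lo: float = 1e-12,
                  hi: float = 16.0, tol: float = 1e-12) -> float:
    """Bisection root of sum_s p(s) exp(lambda s) = 1 on a fixed grid."""

    def f(lam: float) -> float:
        return sum(p * exp(lam * s) for s, p in score_dist.items()) - 1.0

    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
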