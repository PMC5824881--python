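"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (log-gamma /
``math.comb`` arithmetic, full enumeration) and never calls the library code
it is used to check.
"""

from __future__ import annotations

import math
from typing import List, Tuple


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P[X = k] for X ~ Hypergeometric(N, K, n), by log-gamma."""
    if k < max(0, n + K - N) or k > min(K, n):
        return 0.0

    def logc(m: int, r: int) -> float:
        return math.lgamma(m + 1) - math.lgamma(r + 1) - math.lgamma(m - r + 1)

    return math.exp(logc(K, k) + logc(N - K, n - k) - logc(N, n))


def hypergeom_tail_ge(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct summation."""
    return sum(hypergeom_pmf(j, N, K, n) for j in range(k, min(K, n) + 1))


def hypergeom_tail_le(k: int, N: int, K: int, n: int) -> float:
    """P[X <= k] by direct summation."""
    return sum(hypergeom_pmf(j, N, K, n) for j in range(max(0, n + K - N), k + 1))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration over the support.

    Point-probability rule: sum the probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (with a 1e-7 relative slack against floating-point ties).
    """
    N, r1, c1 = a + b + c + d, a + b, a + c
    if N == 0:
        return 1.0
    p_obs = hypergeom_pmf(a, N, r1, c1)
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    total = sum(
        p_k
        for k in range(lo, hi + 1)
        if (p_k := hypergeom_pmf(k, N, r1, c1)) <= p_obs * (1 + 1e-7)
    )
    return min(total, 1.0)


def bh_adjust(p_values: List[float]) -> List[float]:
    """Benjamini-Hochberg step-up by the direct textbook recipe."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = min(p_values[i] * n / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def seed_site_scan(
    sequence: str, word_8mer: str, word_7m8: str, word_7a1: str
) -> List[Tuple[str, int]]:
    """Naive site scan: test every offset independently, then apply
    longest-site precedence.  Returns (site_type, start) pairs."""
    starts_8 = [
        i for i in range(len(sequence) - 7) if sequence[i : i + 8] == word_8mer
    ]
    hits = [("8mer", i) for i in starts_8]
    for i in range(len(sequence) - 6):
        window = sequence[i : i + 7]
        if window == word_7m8 and i not in starts_8:
            hits.append(("7mer-m8", i))
        if window == word_7a1 and (i - 1) not in starts_8:
            hits.append(("7mer-1A", i))
    return sorted(hits, key=lambda h: (h[1], h[0]))
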