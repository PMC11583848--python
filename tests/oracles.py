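"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import factorial


@lru_cache(maxsize=None)
def _table_probs(r1: int, r2: int, n: int) -> tuple[int, tuple[Fraction, ...]]:
    """Exact probabilities of all 2x2 tables with row margins (r1, r2) and
    first-column margin n, enumerated table by table via the factorial formula."""
    m = r1 + r2
    k_lo = max(0, n - r2)
    probs = []
    for a in range(k_lo, min(n, r1) + 1):
        b = n - a
        c, d = r1 - a, r2 - b
        num = factorial(r1) * factorial(r2) * factorial(n) * factorial(m - n)
        den = factorial(m) * factorial(a) * factorial(b) * factorial(c) * factorial(d)
        probs.append(Fraction(num, den))
    return k_lo, tuple(probs)


def fisher_two_sided_oracle(a: int, b: int, r1: int, r2: int) -> float:
    """Two-sided Fisher p for [[a, r1-a], [b, r2-b]] by full enumeration:
    the sum of the probabilities of every table (same margins) no more
    probable than the observed one, in exact rational arithmetic."""
    k_lo, probs = _table_probs(r1, r2, a + b)
    obs = probs[a - k_lo]
    return float(sum(p for p in probs if p <= obs))


def ranksum_greater_oracle(x, y) -> float:
    """One-sided (x greater) rank-sum p by enumerating every assignment of
    the pooled order statistics to the two groups.  Tie-free samples only."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    m, n = len(x), len(y)
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank_of[v] for v in x)
    total = 0
    at_least = 0
    for combo in combinations(range(1, m + n + 1), m):
        total += 1
        if sum(combo) >= w_obs:
            at_least += 1
    return at_least / total
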