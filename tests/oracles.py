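"""Independent brute-force oracles for the exact tests.

Everything here works on exact integers / rationals (``math.comb`` and
``fractions.Fraction``), enumerating the full outcome space, so it shares no
code path with the scipy-backed implementations it checks.
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Minlike two-sided Fisher p for [[a, b], [c, d]] by support enumeration.

    With margins fixed, the table is determined by its top-left cell x; the
    hypergeometric weight of x is C(r1, x) * C(r2, c1 - x) (common factor
    1 / C(n, c1)).  The p-value sums weights of all x whose weight does not
    exceed the observed one — exact integer comparisons, no ties lost.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            total += w
    return Fraction(total, comb(n, c1))


def binomial_two_sided_oracle(k: int, n: int) -> Fraction:
    """Minlike two-sided binomial p at p = 1/2 by pmf enumeration."""
    w_obs = comb(n, k)
    total = sum(comb(n, j) for j in range(n + 1) if comb(n, j) <= w_obs)
    return Fraction(total, 2**n)


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg q-values by direct definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvalues[i] * m / rank)
        q[i] = val
        prev = val
    return q
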