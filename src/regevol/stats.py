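"""Per-gene exact tests, FDR control, and the cis/trans effect arithmetic.

The analysis uses single pooled libraries per genotype, so differential
expression is tested with count-exact statistics rather than replicate-based
models:

* Fisher's exact test of the focal gene's reads against all remaining reads
  (total-expression contrast between two equal-depth libraries);
* exact binomial tests at p = 1/2 for allelic (and mixed-parental) imbalance;
* Fisher's exact test of mixed-parental vs hybrid allelic ratios (the trans
  contrast).

All two-sided p-values follow the "minlike" convention (sum of outcome
probabilities no larger than the observed outcome's), matching
``scipy.stats.fisher_exact`` / ``binomtest`` and R's ``fisher.test`` /
``binom.test``.

Effect sizes: the total expression difference is ``log2(g1/g2)`` from the
mixed-parental pair, the cis effect is ``log2(a1/a2)`` from the hybrid pair,
and the trans effect is their difference, so ``cis + trans == total`` holds
exactly by construction.  ``%cis = 100 |cis| / (|cis| + |trans|)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fet_gene_vs_rest",
    "fet_ratio_difference",
    "binomial_equal_expression",
    "binomial_equal_expression_vec",
    "fet_gene_vs_rest_vec",
    "fet_ratio_difference_vec",
    "bh_fdr",
    "cis_trans_effects",
    "percent_cis",
]


def fet_gene_vs_rest(focal_a: int, focal_b: int, total_a: int, total_b: int) -> float:
    """Two-sided Fisher exact p for one gene's reads vs the rest of the library.

    The 2x2 table is ``[[focal_a, total_a - focal_a], [focal_b,
    total_b - focal_b]]``; the null is equal relative expression in the two
    equal-depth libraries.
    """
    rest_a = total_a - focal_a
    rest_b = total_b - focal_b
    if min(focal_a, focal_b, rest_a, rest_b) < 0:
        raise ValueError("negative margin: focal counts exceed totals")
    return float(
        sps.fisher_exact([[focal_a, rest_a], [focal_b, rest_b]], "two-sided")[1]
    )


def fet_ratio_difference(a1: int, a2: int, b1: int, b2: int) -> float:
    """Two-sided Fisher exact p comparing two count ratios (2x2 table).

    Used for the trans contrast (mixed-parental vs hybrid allelic ratio) and
    for the reciprocal-hybrid imprinting screen.  An all-zero table carries
    no information and returns NaN.
    """
    if min(a1, a2, b1, b2) < 0:
        raise ValueError("counts must be non-negative")
    if a1 + a2 + b1 + b2 == 0:
        return float("nan")
    return float(sps.fisher_exact([[a1, a2], [b1, b2]], "two-sided")[1])


def binomial_equal_expression(k: int, n: int) -> float:
    """Two-sided exact binomial p at success probability 1/2.

    NaN when ``n == 0`` (such genes should have been removed by the 20-read
    floor upstream).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return float("nan")
    return float(sps.binomtest(k, n, 0.5).pvalue)


def binomial_equal_expression_vec(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized :func:`binomial_equal_expression`.

    At p = 1/2 the binomial pmf is symmetric and unimodal, so the minlike
    two-sided p-value collapses to ``2 * P(X <= min(k, n - k))`` (and 1 when
    ``k == n/2``), which vectorizes through the binomial CDF.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any((k < 0) | (k > n)):
        raise ValueError("need 0 <= k <= n")
    m = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.binom.cdf(m, n, 0.5)
    p = np.where(2 * m == n, 1.0, np.minimum(p, 1.0))
    return np.where(n == 0, np.nan, p)


def fet_gene_vs_rest_vec(
    focal_a: np.ndarray, focal_b: np.ndarray, total_a: int, total_b: int
) -> np.ndarray:
    focal_a = np.asarray(focal_a, dtype=np.int64)
    focal_b = np.asarray(focal_b, dtype=np.int64)
    out = np.empty(len(focal_a))
    for i in range(len(focal_a)):
        out[i] = fet_gene_vs_rest(int(focal_a[i]), int(focal_b[i]), total_a, total_b)
    return out


def fet_ratio_difference_vec(
    a1: np.ndarray, a2: np.ndarray, b1: np.ndarray, b2: np.ndarray
) -> np.ndarray:
    a1, a2, b1, b2 = (np.asarray(x, dtype=np.int64) for x in (a1, a2, b1, b2))
    out = np.empty(len(a1))
    for i in range(len(a1)):
        out[i] = fet_ratio_difference(int(a1[i]), int(a2[i]), int(b1[i]), int(b2[i]))
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untested.

    Missing p-values are excluded from the number of tests ``m`` and stay
    missing in the output.  Monotonicity (q non-decreasing in p) and
    ``q >= p`` hold on the tested subset.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def cis_trans_effects(
    g1: np.ndarray, g2: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log2 total, cis, and trans effects from mixed-parental and hybrid pairs.

    ``total = log2(g1/g2)`` (mixed-parental genotype counts), ``cis =
    log2(a1/a2)`` (hybrid allele counts), ``trans = total - cis``.  If one
    member of a pair is zero, 0.5 is added to both members of that pair for
    the point estimate only (the exact tests always use raw counts); a pair
    with both members zero yields NaN.
    """
    def _log2_ratio(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        both_zero = (x == 0) & (y == 0)
        shift = ((x == 0) | (y == 0)) & ~both_zero
        xs = np.where(shift, x + 0.5, x)
        ys = np.where(shift, y + 0.5, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2(xs / ys)
        return np.where(both_zero, np.nan, r)

    total = _log2_ratio(g1, g2)
    cis = _log2_ratio(a1, a2)
    trans = total - cis
    return total, cis, trans


def percent_cis(cis_log2: np.ndarray, trans_log2: np.ndarray) -> np.ndarray:
    """Share of total regulatory divergence attributable to cis, in percent.

    ``100 * |cis| / (|cis| + |trans|)``; NaN when both effects are zero (no
    divergence to apportion) or either is missing.
    """
    c = np.abs(np.asarray(cis_log2, dtype=float))
    t = np.abs(np.asarray(trans_log2, dtype=float))
    denom = c + t
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * c / denom
    return np.where(denom == 0, np.nan, out)
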