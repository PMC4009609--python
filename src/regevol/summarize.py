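"""Genome-scale divergence statistics: 1 - rho, bootstraps, proportion tests.

Overall expression divergence between two genotypes is summarized as
``1 - rho`` where rho is Spearman's rank correlation between the two count
vectors over the filtered gene set (0 = identical ranking, values up to 2).
Rank correlation makes no distributional assumptions and is insensitive to
monotone transforms, which suits depth-normalized count data.

Uncertainty comes from a gene bootstrap: gene index pairs are resampled with
replacement, rho recomputed per replicate, and the 2.5%/97.5% percentiles
reported.  Differences in 1 - rho between two comparisons are assessed two
ways — by the replicate distribution of the difference excluding zero, and
by non-overlap of the two comparisons' own 95% percentile intervals — since
both criteria are in common use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import fet_ratio_difference


def spearman_divergence(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Spearman's rho (average ranks for ties); NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = sps.spearmanr(x, y).statistic
    return float(1.0 - rho)


def _rho(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


@dataclass
class BootstrapRho:
    point: float
    q025: float
    q975: float
    replicates: np.ndarray


def bootstrap_rho(
    x: np.ndarray, y: np.ndarray, n_boot: int = 10_000, seed: int = 0
) -> BootstrapRho:
    """Gene bootstrap of Spearman's rho over paired count vectors.

    Gene indices are resampled jointly (pairs preserved) ``n_boot`` times;
    the point estimate is the plug-in rho on the original data and the
    interval the 2.5%/97.5% percentiles of the replicates.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        reps[b] = _rho(x[idx], y[idx])
    q025, q975 = np.nanpercentile(reps, [2.5, 97.5])
    return BootstrapRho(_rho(x, y), float(q025), float(q975), reps)


@dataclass
class RhoDifference:
    observed_delta: float
    replicates: np.ndarray
    delta_q025: float
    delta_q975: float
    significant_delta_interval: bool
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    significant_quantile_overlap: bool


def bootstrap_rho_difference(
    x_a: np.ndarray,
    y_a: np.ndarray,
    x_b: np.ndarray,
    y_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> RhoDifference:
    """Bootstrap comparison of divergence (1 - rho) between two comparisons.

    Within each replicate the two comparisons are resampled independently
    over their own gene sets and ``delta = (1 - rho_A) - (1 - rho_B)``
    recorded.  Significance is reported under two criteria: the central 95%
    interval of the replicate deltas excluding 0, and the two comparisons'
    own 95% rho intervals not overlapping.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    x_a, y_a, x_b, y_b = (np.asarray(v, dtype=float) for v in (x_a, y_a, x_b, y_b))
    rng = np.random.default_rng(seed)
    n_a, n_b = len(x_a), len(x_b)
    reps = np.empty(n_boot)
    rho_a = np.empty(n_boot)
    rho_b = np.empty(n_boot)
    for b in range(n_boot):
        ia = rng.integers(0, n_a, n_a)
        ib = rng.integers(0, n_b, n_b)
        rho_a[b] = _rho(x_a[ia], y_a[ia])
        rho_b[b] = _rho(x_b[ib], y_b[ib])
        reps[b] = (1.0 - rho_a[b]) - (1.0 - rho_b[b])
    observed = (1.0 - _rho(x_a, y_a)) - (1.0 - _rho(x_b, y_b))
    d_lo, d_hi = np.nanpercentile(reps, [2.5, 97.5])
    a_lo, a_hi = np.nanpercentile(rho_a, [2.5, 97.5])
    b_lo, b_hi = np.nanpercentile(rho_b, [2.5, 97.5])
    return RhoDifference(
        observed_delta=float(observed),
        replicates=reps,
        delta_q025=float(d_lo),
        delta_q975=float(d_hi),
        significant_delta_interval=bool(d_lo > 0 or d_hi < 0),
        interval_a=(float(a_lo), float(a_hi)),
        interval_b=(float(b_lo), float(b_hi)),
        significant_quantile_overlap=bool(a_hi < b_lo or b_hi < a_lo),
    )


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p comparing two proportions k1/n1 vs k2/n2."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n for both proportions")
    return fet_ratio_difference(k1, n1 - k1, k2, n2 - k2)


def cis_total_regression(
    cis_log2: np.ndarray, total_log2: np.ndarray
) -> tuple[float, float, float]:
    """OLS of total expression divergence on the cis effect: (slope, intercept, R2).

    Quantifies how much of the per-gene expression difference the cis
    component explains.  NaNs are dropped pairwise; fewer than 3 finite
    pairs yields NaNs.
    """
    c = np.asarray(cis_log2, dtype=float)
    t = np.asarray(total_log2, dtype=float)
    ok = np.isfinite(c) & np.isfinite(t)
    if ok.sum() < 3:
        return (float("nan"),) * 3
    fit = sps.linregress(c[ok], t[ok])
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
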