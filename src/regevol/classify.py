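"""Categorical calls: regulatory class, inheritance mode, trajectory class.

Regulatory classes combine three significance flags — parental divergence
(binomial test on the mixed-parental pair), cis (binomial test on the hybrid
allelic pair), trans (Fisher test of mixed vs hybrid ratios) — with the
relative signs of the cis and trans effects:

==================  =========================================================
conserved           no test significant
all_cis             parental and cis significant, trans not
all_trans           parental and trans significant, cis not
cis_plus_trans      all three significant, cis and trans same direction
cis_times_trans     all three significant, cis and trans opposite directions
compensatory        cis and trans significant but no parental difference
                    (the effects cancel at the level of total expression)
ambiguous           every remaining combination
==================  =========================================================

Inheritance mode compares hybrid total expression with both parents using
pairwise "different / similar" calls that require both statistical
significance and at least a 1.25-fold difference — the fold floor keeps
small but statistically significant differences (inevitable with exact
tests at high read depth) from driving the biology.

Trajectory classes place each gene's per-comparison expression fold change
(comparisons ordered by divergence time) into one of nine groups according
to whether the difference increased, decreased, or stayed similar between
consecutive comparisons.
"""

from __future__ import annotations

import math

import numpy as np

from .stats import binomial_equal_expression

DEFAULT_FOLD_CUTOFF = 1.25
DEFAULT_FDR = 0.05

REGULATORY_CLASSES = (
    "conserved",
    "all_cis",
    "all_trans",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
    "ambiguous",
)

INHERITANCE_CLASSES = (
    "similar",
    "additive",
    "parent1_dominant",
    "parent2_dominant",
    "overdominant",
    "underdominant",
)

#: (step1, step2) -> trajectory label; steps are in {"increased",
#: "decreased", "similar"}.  I = steadily increasing, II = steadily similar,
#: IIIa-IIIg enumerate the remaining seven patterns in a fixed order.
TRAJECTORY_LABELS = {
    ("increased", "increased"): "I",
    ("similar", "similar"): "II",
    ("increased", "similar"): "IIIa",
    ("decreased", "similar"): "IIIb",
    ("increased", "decreased"): "IIIc",
    ("decreased", "increased"): "IIId",
    ("similar", "increased"): "IIIe",
    ("similar", "decreased"): "IIIf",
    ("decreased", "decreased"): "IIIg",
}


def fold_change(a: float, b: float) -> float:
    """Linear fold difference max(a, b) / min(a, b), >= 1; 1 when both zero."""
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a == b:
        return 1.0
    lo, hi = sorted((a, b))
    return math.inf if lo == 0 else hi / lo


def pairwise_difference_call(
    count_a: float,
    count_b: float,
    q_value: float,
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF,
    fdr: float = DEFAULT_FDR,
) -> str:
    """"different_up" / "different_down" / "similar" for one genotype pair.

    "Different" requires BOTH a significant exact test (q <= fdr) and a fold
    difference of at least ``fold_cutoff`` (differences less than the cutoff
    are considered similar, so the boundary fold itself counts as
    different).  Direction follows the sign of ``count_a - count_b``.
    """
    if not (np.isnan(q_value) or 0 <= q_value <= 1):
        raise ValueError("q_value outside [0, 1]")
    if np.isnan(q_value) or q_value > fdr:
        return "similar"
    if fold_change(count_a, count_b) < fold_cutoff:
        return "similar"
    return "different_up" if count_a > count_b else "different_down"


def classify_regulatory(
    sig_parental: bool,
    sig_cis: bool,
    sig_trans: bool,
    cis_log2: float,
    trans_log2: float,
) -> str:
    """One regulatory class from the three significance flags and effect signs."""
    for flag in (sig_parental, sig_cis, sig_trans):
        if flag is None or (isinstance(flag, float) and np.isnan(flag)):
            return "ambiguous"
    if not (sig_parental or sig_cis or sig_trans):
        return "conserved"
    if sig_parental and sig_cis and not sig_trans:
        return "all_cis"
    if sig_parental and sig_trans and not sig_cis:
        return "all_trans"
    if sig_cis and sig_trans and not sig_parental:
        return "compensatory"
    if sig_parental and sig_cis and sig_trans:
        sc, st = np.sign(cis_log2), np.sign(trans_log2)
        if sc == 0 or st == 0 or np.isnan(sc) or np.isnan(st):
            return "ambiguous"
        return "cis_plus_trans" if sc == st else "cis_times_trans"
    return "ambiguous"


def direction_concordance(cis_log2: float, trans_log2: float) -> str | None:
    """"same" / "opposite" sign concordance; None unless both effects nonzero."""
    sc, st = np.sign(cis_log2), np.sign(trans_log2)
    if sc == 0 or st == 0 or np.isnan(sc) or np.isnan(st):
        return None
    return "same" if sc == st else "opposite"


def classify_inheritance(
    call_p1_p2: str,
    call_h_p1: str,
    call_h_p2: str,
    p1_count: float,
    p2_count: float,
    h_count: float,
) -> str:
    """Inheritance mode of hybrid total expression relative to the parents.

    * similar — hybrid similar to both parents (regardless of the parental
      contrast, which the fold rule can leave "different" while the hybrid
      sits indistinguishably between the parents; such genes are still
      reported as similar, the conservative call);
    * parentX_dominant — similar to parent X only;
    * additive — different from both and strictly between them;
    * over-/under-dominant (misexpression) — different from both and above /
      below the more extreme / lesser parental level.  A hybrid count exactly
      equal to a parent's is treated as resembling that parent.
    """
    h_sim_p1 = call_h_p1 == "similar"
    h_sim_p2 = call_h_p2 == "similar"
    del call_p1_p2  # the parental contrast never overrides the hybrid calls
    if h_sim_p1 and h_sim_p2:
        return "similar"
    if h_sim_p1:
        return "parent1_dominant"
    if h_sim_p2:
        return "parent2_dominant"
    lo, hi = sorted((p1_count, p2_count))
    if h_count > hi:
        return "overdominant"
    if h_count < lo:
        return "underdominant"
    if h_count == p1_count:
        return "parent1_dominant"
    if h_count == p2_count:
        return "parent2_dominant"
    return "additive"


def trajectory_step(
    fold_prev: float, fold_next: float, cutoff: float = DEFAULT_FOLD_CUTOFF
) -> str:
    """Direction of change of an expression difference between two comparisons.

    Similar when the two linear fold changes differ by less than ``cutoff``
    (i.e. ``max/min < cutoff``); otherwise increased/decreased by which is
    larger.
    """
    if fold_prev < 1 or fold_next < 1:
        raise ValueError("fold changes must be >= 1")
    if fold_prev == fold_next:
        return "similar"
    lo, hi = sorted((fold_prev, fold_next))
    ratio = math.inf if lo == 0 else hi / lo
    if ratio < cutoff:
        return "similar"
    return "increased" if fold_next > fold_prev else "decreased"


def classify_trajectory(
    folds: tuple[float, float, float], cutoff: float = DEFAULT_FOLD_CUTOFF
) -> tuple[str, str, str]:
    """Nine-way trajectory class from three ordered per-comparison folds.

    Returns ``(step1, step2, label)`` where the steps compare comparison 1
    to 2 and 2 to 3.
    """
    if len(folds) != 3 or any(f is None or np.isnan(f) for f in folds):
        raise ValueError("trajectory classification needs three fold changes")
    s1 = trajectory_step(folds[0], folds[1], cutoff)
    s2 = trajectory_step(folds[1], folds[2], cutoff)
    return s1, s2, TRAJECTORY_LABELS[(s1, s2)]


def direction_concordance_test(n_same: int, n_opposite: int) -> float:
    """Two-sided exact binomial p that same/opposite directions are equally likely.

    Applied to genes with both cis and trans effects significant; NaN when
    no such genes exist.
    """
    if n_same < 0 or n_opposite < 0:
        raise ValueError("counts must be non-negative")
    n = n_same + n_opposite
    if n == 0:
        return float("nan")
    return binomial_equal_expression(n_same, n)
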