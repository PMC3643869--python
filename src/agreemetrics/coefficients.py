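"""Chance-corrected agreement coefficients for a 2x2 two-rater table.

Implements percent agreement, Cohen's Kappa and Gwet's first-order
agreement coefficient (AC1), together with their chance-agreement terms
and standard errors.

Both coefficients share the form ``(p - p_e) / (1 - p_e)`` where ``p`` is
the observed proportion of agreeing subjects; they differ only in the
chance term:

* Kappa uses the product of the two raters' marginal distributions,
  ``e_K = (a1*b1 + a2*b2) / n^2``, which can approach 1 when marginals
  are concentrated — the source of the "kappa paradox" where near-total
  observed agreement yields a Kappa near 0.
* AC1 uses ``e_g = 2 q (1 - q)`` with ``q = (a1 + b1) / (2n)`` the mean
  category-1 propensity across the raters; this chance term is
  structurally bounded by 0.5, keeping AC1 close to percent agreement
  even under extreme prevalence.

Standard errors follow Gwet's subject-level linearization for two raters
(no finite-population correction), and a leave-one-subject-out jackknife
is provided as an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Literal

from .contingency import ContingencyTable, RatingDataError

Method = Literal["percent_agreement", "cohen_kappa", "gwet_ac1"]
DegenerateFlag = Literal["none", "perfect_agreement", "kappa_zero_marginal"]


@dataclass(frozen=True)
class AgreementEstimate:
    """A single agreement coefficient with its chance term and SE.

    Attributes
    ----------
    method
        Which statistic this is.
    estimate
        The point estimate (in [-1, 1]; percent agreement in [0, 1]).
    chance_agreement
        The chance term p_e (None for percent agreement).
    se
        Analytic standard error (None when not requested / undefined).
    n
        Number of subjects.
    degenerate_flag
        ``perfect_agreement`` when the 0/0 convention Kappa := 1 was
        applied (all mass in one agreement cell); ``kappa_zero_marginal``
        when a fully concentrated marginal forces Kappa to exactly 0
        despite imperfect agreement.
    """

    method: Method
    estimate: float
    chance_agreement: float | None
    se: float | None
    n: int
    degenerate_flag: DegenerateFlag = "none"

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval, truncated to [-1, 1]."""
        if self.se is None:
            raise ValueError("no standard error available for a confidence interval")
        # 1.96 for 95%; use the normal quantile for other levels
        from statistics import NormalDist

        z = NormalDist().inv_cdf(0.5 + level / 2)
        return (max(-1.0, self.estimate - z * self.se), min(1.0, self.estimate + z * self.se))


# ---------------------------------------------------------------------
# point estimates (exact rational arithmetic, floats only at the edge)
# ---------------------------------------------------------------------

def percent_agreement(table: ContingencyTable, compute_se: bool = False) -> AgreementEstimate:
    """Observed proportion of subjects on which the raters agree."""
    p = Fraction(table.a + table.d, table.n)
    se = None
    if compute_se:
        if table.n < 2:
            raise RatingDataError("standard error requires at least two subjects")
        pf = float(p)
        se = math.sqrt(pf * (1 - pf) / (table.n - 1))
    return AgreementEstimate("percent_agreement", float(p), None, se, table.n)


def kappa_chance_agreement(table: ContingencyTable) -> float:
    """Kappa's chance term: the product-marginal agreement probability."""
    return float(_kappa_pe(table))


def _kappa_pe(table: ContingencyTable) -> Fraction:
    n = table.n
    return Fraction(table.a1 * table.b1 + table.a2 * table.b2, n * n)


def gwet_q(table: ContingencyTable) -> float:
    """Mean category-1 marginal proportion across the two raters."""
    return float(Fraction(table.a1 + table.b1, 2 * table.n))


def ac1_chance_agreement(table: ContingencyTable) -> float:
    """AC1's chance term 2q(1-q); at most 0.5 (attained at q = 1/2)."""
    return float(_ac1_pe(table))


def _ac1_pe(table: ContingencyTable) -> Fraction:
    q = Fraction(table.a1 + table.b1, 2 * table.n)
    return 2 * q * (1 - q)


def cohen_kappa(table: ContingencyTable, compute_se: bool = True) -> AgreementEstimate:
    """Cohen's Kappa with the degenerate-marginal conventions.

    When every subject falls in a single agreement cell both p and e(K)
    equal 1; the indeterminate 0/0 is resolved to 1.0 (flagged
    ``perfect_agreement``).  When one rater's marginal is fully
    concentrated but agreement is imperfect, the formula collapses to
    exactly 0 (flagged ``kappa_zero_marginal``).
    """
    p = Fraction(table.a + table.d, table.n)
    pe = _kappa_pe(table)
    flag: DegenerateFlag = "none"
    if pe == 1:
        # all four counts in one cell on the diagonal, or a degenerate
        # split that concentrates both marginals
        if p == 1:
            est = Fraction(1)
            flag = "perfect_agreement"
        else:
            # both raters constant but disagreeing (e.g. b=n): kappa 0
            est = Fraction(0)
            flag = "kappa_zero_marginal"
    else:
        est = (p - pe) / (1 - pe)
        if est == 0 and p < 1 and 0 in (table.a1, table.a2, table.b1, table.b2):
            flag = "kappa_zero_marginal"
    se = None
    if compute_se and table.n >= 2:
        se = 0.0 if flag == "perfect_agreement" else kappa_se(table)
    return AgreementEstimate(
        "cohen_kappa", float(est), float(pe), se, table.n, degenerate_flag=flag
    )


def gwet_ac1(table: ContingencyTable, compute_se: bool = True) -> AgreementEstimate:
    """Gwet's AC1; no special-casing needed (e_g < 1 always for n >= 1)."""
    p = Fraction(table.a + table.d, table.n)
    pe = _ac1_pe(table)
    est = (p - pe) / (1 - pe)
    flag: DegenerateFlag = "perfect_agreement" if p == 1 and _kappa_pe(table) == 1 else "none"
    se = None
    if compute_se and table.n >= 2:
        se = ac1_se(table)
    return AgreementEstimate(
        "gwet_ac1", float(est), float(pe), se, table.n, degenerate_flag=flag
    )


# ---------------------------------------------------------------------
# variance estimators (Gwet's subject-level linearization, two raters)
# ---------------------------------------------------------------------
#
# Each subject falls in one of the four cells; the influence of a subject
# on the coefficient depends only on its cell, so the variance sums over
# cells weighted by counts:
#
#   var = 1/n^2 * sum_i (s_i - s_bar)^2,
#   s_i = k_i - 2 (1 - est) (pe_i - pe) / (1 - pe),
#   k_i = (agree_i - pe) / (1 - pe),
#
# where pe_i is the subject-level chance term:
#   Kappa: pe_i = (r1_i(cat) dotted with rater2 marginals
#                  + r2_i(cat) dotted with rater1 marginals) / 2
#   AC1:   pe_i = pi_i(cat1) (1 - pi(cat1)) + pi_i(cat2) (1 - pi(cat2)),
#          pi_i(k) = (r1_i(k) + r2_i(k)) / 2
#
# No finite-population correction is applied.

def _cell_profiles(table: ContingencyTable):
    """Per-cell (count, agree, rater1-cat1 indicator, rater2-cat1 indicator)."""
    return [
        (table.a, 1.0, 1.0, 1.0),
        (table.b, 0.0, 0.0, 1.0),
        (table.c, 0.0, 1.0, 0.0),
        (table.d, 1.0, 0.0, 0.0),
    ]


def kappa_se(table: ContingencyTable) -> float:
    """Analytic standard error of Cohen's Kappa (linearization)."""
    n = table.n
    if n < 2:
        raise RatingDataError("standard error requires at least two subjects")
    pe = float(_kappa_pe(table))
    if pe == 1.0:
        return 0.0
    est = cohen_kappa(table, compute_se=False).estimate
    p1 = table.a1 / n  # rater 1 category-1 marginal
    p2 = table.b1 / n  # rater 2 category-1 marginal
    total = 0.0
    for count, agree, r1c1, r2c1 in _cell_profiles(table):
        if count == 0:
            continue
        # subject-level chance term: average of each rater's indicator
        # dotted with the *other* rater's marginal distribution
        pe_i = 0.5 * (
            r1c1 * p2 + (1 - r1c1) * (1 - p2) + r2c1 * p1 + (1 - r2c1) * (1 - p1)
        )
        k_i = (agree - pe) / (1 - pe)
        s_i = k_i - 2 * (1 - est) * (pe_i - pe) / (1 - pe)
        total += count * (s_i - est) ** 2
    # 1/n^2 normalization: for kappa this linearized estimator is
    # algebraically identical to the Fleiss-Cohen-Everitt (1969)
    # large-sample variance
    return math.sqrt(total) / n


def ac1_se(table: ContingencyTable) -> float:
    """Analytic standard error of Gwet's AC1 (linearization)."""
    n = table.n
    if n < 2:
        raise RatingDataError("standard error requires at least two subjects")
    pe = float(_ac1_pe(table))
    est = gwet_ac1(table, compute_se=False).estimate
    q = gwet_q(table)  # mean category-1 propensity
    total = 0.0
    for count, agree, r1c1, r2c1 in _cell_profiles(table):
        if count == 0:
            continue
        pi1_i = 0.5 * (r1c1 + r2c1)  # subject-level category-1 propensity
        pe_i = pi1_i * (1 - q) + (1 - pi1_i) * q
        g_i = (agree - pe) / (1 - pe)
        s_i = g_i - 2 * (1 - est) * (pe_i - pe) / (1 - pe)
        total += count * (s_i - est) ** 2
    return math.sqrt(total) / n


def jackknife_se(table: ContingencyTable, method: Method) -> float:
    """Leave-one-subject-out jackknife SE — independent of the analytic path.

    Recomputes the chosen coefficient on each of the ``n`` tables obtained
    by deleting one subject, then applies the standard jackknife formula
    ``sqrt((n-1)/n * sum (theta_(i) - theta_bar)^2)``.
    """
    n = table.n
    if n < 2:
        raise RatingDataError("jackknife requires at least two subjects")
    stat = _point_estimator(method)
    reps: list[float] = []
    weights: list[int] = []
    for idx, count in enumerate(table.cells):
        if count == 0:
            continue
        cells = list(table.cells)
        cells[idx] -= 1
        reps.append(stat(ContingencyTable(*cells, labels=table.labels)))
        weights.append(count)
    total_w = sum(weights)
    mean = sum(w * r for w, r in zip(weights, reps)) / total_w
    ss = sum(w * (r - mean) ** 2 for w, r in zip(weights, reps))
    return math.sqrt((n - 1) / n * ss)


def _point_estimator(method: Method) -> Callable[[ContingencyTable], float]:
    if method == "percent_agreement":
        return lambda t: percent_agreement(t).estimate
    if method == "cohen_kappa":
        return lambda t: cohen_kappa(t, compute_se=False).estimate
    if method == "gwet_ac1":
        return lambda t: gwet_ac1(t, compute_se=False).estimate
    raise ValueError(f"unknown method {method!r}")
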