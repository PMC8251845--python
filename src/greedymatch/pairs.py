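"""Analysis of one matched set: conditional OR, covariate balance, crude OR.

For 1:1 matched pairs and a treatment-only model, conditional logistic
regression has a closed-form maximum-likelihood solution: concordant pairs
(both or neither member with the outcome) drop out of the conditional
likelihood, and the OR estimate is the ratio n10/n01 of discordant-pair
counts, with Wald 95% CI exp(ln(n10/n01) +/- 1.96*sqrt(1/n10 + 1/n01)).
Using the closed form removes iterative-fit convergence noise from a study
that performs tens of thousands of such fits; the generic numeric maximiser
is retained in the test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgp import Cohort
from .matching import MatchedSet

__all__ = ["PairedEstimate", "BalanceReport", "conditional_or", "balance", "crude_or"]

_Z975 = 1.959963984540054  # standard normal 97.5% quantile

#: Matched sets with any covariate SMD above this are "unsuccessful".
SMD_THRESHOLD = 0.1


@dataclass
class PairedEstimate:
    """Conditional-logistic treatment-outcome OR from one matched set."""

    or_hat: float
    ci_low: float
    ci_high: float
    n10: int          # pairs with treated outcome 1, control outcome 0
    n01: int          # the reverse discordance
    defined: bool
    significant_low: bool    # 95% CI entirely below 1
    significant_high: bool   # 95% CI entirely above 1


@dataclass
class BalanceReport:
    """Absolute standardized mean differences after matching."""

    smd: np.ndarray
    successful: bool

    @property
    def max_smd(self) -> float:
        return float(np.max(self.smd)) if self.smd.size else 0.0


def conditional_or(matched: MatchedSet, cohort: Cohort) -> PairedEstimate:
    """Treatment-outcome OR by conditional logistic regression on 1:1 pairs.

    If either discordant count is zero the MLE sits on the boundary and the
    estimate is reported as undefined (no Haldane-type correction).
    """
    if matched.n_pairs == 0:
        raise ValueError("cannot estimate an OR from an empty matched set")
    y_t = cohort.y[matched.pairs[:, 0]]
    y_c = cohort.y[matched.pairs[:, 1]]
    n10 = int(np.sum((y_t == 1) & (y_c == 0)))
    n01 = int(np.sum((y_t == 0) & (y_c == 1)))
    if n10 == 0 or n01 == 0:
        return PairedEstimate(
            or_hat=np.nan, ci_low=np.nan, ci_high=np.nan,
            n10=n10, n01=n01, defined=False,
            significant_low=False, significant_high=False,
        )
    log_or = np.log(n10 / n01)
    se = np.sqrt(1.0 / n10 + 1.0 / n01)
    ci_low = float(np.exp(log_or - _Z975 * se))
    ci_high = float(np.exp(log_or + _Z975 * se))
    return PairedEstimate(
        or_hat=float(n10 / n01), ci_low=ci_low, ci_high=ci_high,
        n10=n10, n01=n01, defined=True,
        significant_low=ci_high < 1.0, significant_high=ci_low > 1.0,
    )


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """|mean(a) - mean(b)| / sqrt((var(a) + var(b)) / 2), sample variances.

    Degenerate denominators: equal means with zero spread give 0; unequal
    means with zero spread give +inf (an unambiguous imbalance).
    """
    diff = abs(float(a.mean()) - float(b.mean()))
    if a.size > 1:
        va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    else:
        va = vb = 0.0
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return diff / denom


def balance(matched: MatchedSet, cohort: Cohort) -> BalanceReport:
    """Post-matching covariate balance between matched treated and controls.

    Binary covariates enter as 0/1 means.  A set is successful when every
    covariate's SMD is at or below 0.1.
    """
    if matched.n_pairs == 0:
        raise ValueError("cannot assess balance of an empty matched set")
    Xt = cohort.X[matched.pairs[:, 0]]
    Xc = cohort.X[matched.pairs[:, 1]]
    smd = np.array([_smd(Xt[:, j], Xc[:, j]) for j in range(cohort.X.shape[1])])
    return BalanceReport(smd=smd, successful=bool(np.all(smd <= SMD_THRESHOLD)))


def crude_or(cohort: Cohort) -> float:
    """Unadjusted OR from the full-cohort 2x2 treatment-by-outcome table.

    Returns NaN (undefined) when any cell of the table is empty.
    """
    t, y = cohort.t, cohort.y
    n11 = int(np.sum((t == 1) & (y == 1)))
    n10 = int(np.sum((t == 1) & (y == 0)))
    n01 = int(np.sum((t == 0) & (y == 1)))
    n00 = int(np.sum((t == 0) & (y == 0)))
    if min(n11, n10, n01, n00) == 0:
        return float("nan")
    return (n11 * n00) / (n10 * n01)
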