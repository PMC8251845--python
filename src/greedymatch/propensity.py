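"""Propensity-score estimation and caliper derivation.

The propensity score is the fitted probability of treatment from a
maximum-likelihood logistic regression of treatment on all baseline
covariates.  Caliper widths are multiples of the standard deviation of the
estimated scores over the full cohort, computed before any matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .dgp import Cohort

__all__ = ["PropensityFit", "fit_propensity", "caliper_width"]

try:  # raised (not warned) by some statsmodels optimisers
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass


@dataclass
class PropensityFit:
    """A fitted propensity model and its derived quantities.

    ``coefficients`` holds the intercept followed by one log-odds coefficient
    per covariate (zero for covariates dropped as constant).  ``ps`` are the
    fitted treatment probabilities for every subject; ``sd_ps`` is their
    sample standard deviation (denominator n-1) over the whole cohort,
    treated and untreated pooled.
    """

    coefficients: np.ndarray
    ps: np.ndarray
    sd_ps: float
    converged: bool

    def scores(self, scale: str = "probability") -> np.ndarray:
        """Matching scores on the probability (default) or logit scale."""
        if scale == "probability":
            return self.ps
        if scale == "logit":
            return logit(self.ps)
        raise ValueError(f"unknown score scale {scale!r}")

    def score_sd(self, scale: str = "probability") -> float:
        if scale == "probability":
            return self.sd_ps
        return float(np.std(self.scores(scale), ddof=1))

    def to_frame(self, cohort: Cohort) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(cohort.n),
            "t": cohort.t,
            "y": cohort.y,
            "ps": self.ps,
        })


def fit_propensity(cohort: Cohort, *, tol: float = 1e-8, maxiter: int = 100) -> PropensityFit:
    """Fit the propensity model by Newton-type maximum likelihood.

    Constant covariate columns carry no information and are dropped from the
    design (their reported coefficient is 0); with every column constant the
    fit reduces to the intercept-only model, whose fitted probability is the
    treatment prevalence.  Separation is reported through ``converged=False``
    rather than silently returning divergent estimates.
    """
    t = cohort.t
    n_treated = int(t.sum())
    if n_treated == 0 or n_treated == cohort.n:
        raise ValueError("propensity model needs both treated and untreated subjects")

    keep = np.flatnonzero(np.ptp(cohort.X, axis=0) > 0)
    exog = np.column_stack([np.ones(cohort.n), cohort.X[:, keep]])

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(t, exog).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=0,
            )
        converged = bool(res.mle_retvals.get("converged", False))
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        # fall back to a damped quasi-Newton pass so scores remain usable,
        # but flag the fit as unreliable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(t, exog).fit(method="bfgs", maxiter=200, disp=0)
        converged = False

    coef = np.zeros(cohort.X.shape[1] + 1)
    coef[0] = res.params[0]
    coef[1 + keep] = res.params[1:]
    ps = np.asarray(res.predict(exog), dtype=float)
    sd_ps = float(np.std(ps, ddof=1)) if cohort.n > 1 else 0.0
    return PropensityFit(coefficients=coef, ps=ps, sd_ps=sd_ps, converged=converged)


def caliper_width(fit: PropensityFit, multiplier: float, *, scale: str = "probability") -> float:
    """Caliper width = multiplier x SD of the matching scores (0.2 and 0.01
    are the study's values)."""
    if not (multiplier > 0):
        raise ValueError(f"caliper multiplier must be positive, got {multiplier}")
    sd = fit.score_sd(scale)
    if sd <= 0:
        raise ValueError("caliper undefined: propensity scores are constant")
    return multiplier * sd
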