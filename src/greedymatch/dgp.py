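"""Synthetic cohort generation for the matching-variability study.

The data-generating process is a confounded binary-treatment / binary-outcome
design: eight mutually independent baseline covariates (six Bernoulli(0.2),
two Normal(0, 0.5)), a main-effects logistic treatment model and a
main-effects logistic outcome model that includes the treatment.  Covariate
effects are parameterised as odds ratios; model intercepts are not free
parameters but are calibrated numerically so that the marginal treatment and
outcome prevalences hit their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "CovariateSpec",
    "Scenario",
    "Cohort",
    "CalibrationError",
    "default_covariates",
    "simulate_covariates",
    "calibrate_intercept",
    "scenario_intercepts",
    "simulate_cohort",
]

#: Seed of the calibration sample.  Fixed and independent of every analysis
#: seed so that intercept calibration never couples two runs.
CALIBRATION_SEED = 915_148_801

#: Size of the Monte-Carlo sample used to calibrate intercepts.
CALIBRATION_SIZE = 1_000_000


class CalibrationError(RuntimeError):
    """Raised when an intercept cannot be bracketed in log-odds [-20, 20]."""


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate of the generating model.

    Parameters
    ----------
    name : str
        Column label, e.g. ``"x3"``.
    kind : {"binary", "continuous"}
        Bernoulli or Normal marginal distribution.
    prevalence : float, optional
        Success probability in (0, 1] (binary only; 1 allowed as the
        degenerate constant column).
    mean, variance : float, optional
        Normal parameters (continuous only); variance must be positive.
    or_treatment, or_outcome : float
        Per-unit odds ratios of the covariate in the treatment and outcome
        models.  Coefficients are their natural logs, so an OR of 1 means a
        coefficient of exactly 0.
    """

    name: str
    kind: str
    prevalence: float | None = None
    mean: float | None = None
    variance: float | None = None
    or_treatment: float = 1.0
    or_outcome: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"covariate {self.name}: unknown kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence <= 1.0):
                raise ValueError(
                    f"covariate {self.name}: binary prevalence must lie in (0, 1], "
                    f"got {self.prevalence!r}"
                )
        else:
            if self.mean is None or self.variance is None or self.variance <= 0:
                raise ValueError(
                    f"covariate {self.name}: continuous covariates need a mean and "
                    f"a positive variance, got mean={self.mean!r} "
                    f"variance={self.variance!r}"
                )
        for label, value in (("or_treatment", self.or_treatment),
                             ("or_outcome", self.or_outcome)):
            if not (value > 0 and np.isfinite(value)):
                raise ValueError(
                    f"covariate {self.name}: {label} must be a positive finite "
                    f"odds ratio, got {value!r}"
                )


def default_covariates() -> tuple[CovariateSpec, ...]:
    """The study's standard eight-covariate specification.

    Six independent binary covariates with prevalence 0.2 and two independent
    Normal(0, 0.5) covariates, with treatment-model odds ratios
    (2, 1, 0.5, 2, 1, 0.5, 1.5, 0.5) and outcome-model odds ratios
    (1, 2, 0.5, 0.5, 1, 2, 0.5, 1.5).
    """
    or_t = (2.0, 1.0, 0.5, 2.0, 1.0, 0.5, 1.5, 0.5)
    or_y = (1.0, 2.0, 0.5, 0.5, 1.0, 2.0, 0.5, 1.5)
    specs = []
    for k in range(6):
        specs.append(CovariateSpec(
            name=f"x{k + 1}", kind="binary", prevalence=0.2,
            or_treatment=or_t[k], or_outcome=or_y[k],
        ))
    for k in range(6, 8):
        specs.append(CovariateSpec(
            name=f"x{k + 1}", kind="continuous", mean=0.0, variance=0.5,
            or_treatment=or_t[k], or_outcome=or_y[k],
        ))
    return tuple(specs)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid.

    The study grid crosses cohort size {500, 2500, 10000}, treatment
    prevalence {0.2, 0.5}, outcome prevalence {0.1, 0.5} and true treatment
    odds ratio {0.75, 1.0, 1.5}; arbitrary values are accepted for
    exploration.
    """

    n: int
    p_treat: float
    p_outcome: float
    true_or: float
    covariates: tuple[CovariateSpec, ...] = field(default_factory=default_covariates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        for label, p in (("p_treat", self.p_treat), ("p_outcome", self.p_outcome)):
            if not (0.0 < p < 1.0):
                raise ValueError(f"{label} must lie in (0, 1), got {p}")
        if not (self.true_or > 0 and np.isfinite(self.true_or)):
            raise ValueError(f"true_or must be positive and finite, got {self.true_or}")
        if len(self.covariates) == 0:
            raise ValueError("at least one covariate is required")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def label(self) -> str:
        return (f"n{self.n}_t{round(self.p_treat * 100)}"
                f"_o{round(self.p_outcome * 100)}_or{self.true_or:g}")

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=int(seed))


@dataclass
class Cohort:
    """A simulated cohort: covariates, treatment and outcome indicators."""

    X: np.ndarray           # (n, k) float matrix
    t: np.ndarray           # (n,) 0/1 treatment
    y: np.ndarray           # (n,) 0/1 outcome
    covariate_names: tuple[str, ...]
    alpha0: float | None = None   # calibrated treatment-model intercept
    beta0: float | None = None    # calibrated outcome-model intercept

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.t = np.asarray(self.t, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        n = self.X.shape[0]
        if self.t.shape != (n,) or self.y.shape != (n,):
            raise ValueError("t and y must be length-n vectors")
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names must match X's column count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_treated(self) -> int:
        return int(self.t.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.covariate_names))
        df["t"] = self.t
        df["y"] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        names = [c for c in df.columns if c not in ("t", "y")]
        if "t" not in df.columns or "y" not in df.columns:
            raise ValueError("cohort frame needs 't' and 'y' columns")
        return cls(
            X=df[names].to_numpy(dtype=float),
            t=df["t"].to_numpy(dtype=np.int64),
            y=df["y"].to_numpy(dtype=np.int64),
            covariate_names=tuple(names),
        )

    def to_csv(self, path) -> None:
        # pandas' default float formatting is the shortest exact repr, so the
        # write/read round trip is bit-exact
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def simulate_covariates(
    specs: Sequence[CovariateSpec], n: int, rng: Generator
) -> np.ndarray:
    """Draw an ``n x k`` matrix of independent covariates, one column per spec."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cols = np.empty((n, len(specs)), dtype=float)
    for j, spec in enumerate(specs):
        if spec.kind == "binary":
            cols[:, j] = rng.random(n) < spec.prevalence
        else:
            cols[:, j] = rng.normal(spec.mean, np.sqrt(spec.variance), size=n)
    return cols


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Root of mean(expit(c + eta)) = target over log-odds c in [-20, 20].

    The expectation is strictly increasing in c, so the bracketed root is
    unique when it exists.
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target prevalence must lie in (0, 1), got {target}")

    def gap(c: float) -> float:
        return float(expit(c + eta).mean()) - target

    lo, hi = -20.0, 20.0
    if gap(lo) > 0.0 or gap(hi) < 0.0:
        raise CalibrationError(
            f"cannot bracket intercept for target prevalence {target} "
            f"within log-odds [{lo}, {hi}]"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def calibrate_intercept(
    coeffs: Sequence[float],
    specs: Sequence[CovariateSpec],
    target_prevalence: float,
    *,
    extra_logodds: np.ndarray | None = None,
    size: int = CALIBRATION_SIZE,
    seed: int = CALIBRATION_SEED,
) -> float:
    """Calibrate a logistic-model intercept to a target marginal prevalence.

    Draws a deterministic calibration sample from ``specs``, forms the linear
    predictor ``X @ coeffs`` (plus ``extra_logodds`` per subject if given,
    e.g. a realised treatment term) and solves for the intercept whose
    Monte-Carlo mean response probability equals ``target_prevalence``.
    """
    if len(coeffs) != len(specs):
        raise ValueError("one coefficient per covariate is required")
    X = simulate_covariates(specs, size, default_rng(seed))
    eta = X @ np.asarray(coeffs, dtype=float)
    if extra_logodds is not None:
        eta = eta + extra_logodds
    return _solve_intercept(eta, target_prevalence)


@lru_cache(maxsize=128)
def _intercepts_cached(
    covariates: tuple[CovariateSpec, ...],
    p_treat: float,
    p_outcome: float,
    true_or: float,
    size: int,
    seed: int,
) -> tuple[float, float]:
    rng = default_rng(seed)
    X = simulate_covariates(covariates, size, rng)
    log_or_t = np.log([s.or_treatment for s in covariates])
    log_or_y = np.log([s.or_outcome for s in covariates])

    eta_t = X @ log_or_t
    alpha0 = _solve_intercept(eta_t, p_treat)

    # Outcome calibration targets the MARGINAL outcome prevalence: the
    # calibration subjects receive treatment from the already-calibrated
    # treatment model, and the realised beta_T * T term enters the linear
    # predictor before the outcome intercept is solved.
    t_cal = rng.random(size) < expit(alpha0 + eta_t)
    eta_y = X @ log_or_y + np.log(true_or) * t_cal
    beta0 = _solve_intercept(eta_y, p_outcome)
    return alpha0, beta0


def scenario_intercepts(
    scenario: Scenario,
    *,
    size: int = CALIBRATION_SIZE,
    seed: int = CALIBRATION_SEED,
) -> tuple[float, float]:
    """Calibrated (treatment, outcome) intercepts for a scenario.

    Cached, since the intercepts depend only on the covariate specification
    and the prevalence/effect targets, never on the cohort seed or size.
    """
    return _intercepts_cached(
        scenario.covariates, scenario.p_treat, scenario.p_outcome,
        scenario.true_or, size, seed,
    )


def simulate_cohort(scenario: Scenario) -> Cohort:
    """Simulate one cohort under a scenario.

    Covariates are drawn first; treatment is Bernoulli under the logistic
    treatment model with the calibrated intercept; the outcome is Bernoulli
    under the logistic outcome model given covariates and realised treatment.
    Identical scenarios (including seed) give bitwise-identical cohorts.
    """
    alpha0, beta0 = scenario_intercepts(scenario)
    rng = default_rng(scenario.seed)
    X = simulate_covariates(scenario.covariates, scenario.n, rng)
    log_or_t = np.log([s.or_treatment for s in scenario.covariates])
    log_or_y = np.log([s.or_outcome for s in scenario.covariates])
    t = (rng.random(scenario.n) < expit(alpha0 + X @ log_or_t)).astype(np.int64)
    p_y = expit(beta0 + X @ log_or_y + np.log(scenario.true_or) * t)
    y = (rng.random(scenario.n) < p_y).astype(np.int64)
    return Cohort(
        X=X, t=t, y=y,
        covariate_names=tuple(s.name for s in scenario.covariates),
        alpha0=alpha0, beta0=beta0,
    )
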