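"""Repeated-matching experiment: model and results objects, grid runner.

The central object is :class:`RepeatedMatching`, a model in the
statsmodels mould: it is built from a cohort (simulated or supplied as a
DataFrame) together with a matching configuration, and its :meth:`fit`
re-runs the greedy matching ``reps`` times with distinct seeds — a fresh
random treated-subject ordering each repetition — estimating the
treatment-outcome OR by conditional logistic regression in every matched
set.  The returned :class:`RepeatedMatchingResults` summarises the spread of
the estimates across repetitions (median, IQR, full range), the share of
repetitions reaching significance in either direction, the mean number of
matched subjects and the share of repetitions failing the SMD <= 0.1 balance
rule.  The propensity model is fitted once per cohort and shared by all
repetitions, mirroring the study design of repeating only the matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .dgp import Cohort, Scenario, simulate_cohort
from .matching import MATCHERS, MatchConfig
from .pairs import balance, conditional_or, crude_or
from .propensity import PropensityFit, fit_propensity

__all__ = [
    "QUANTILE_CONVENTION",
    "ReplicationSummary",
    "RepeatedMatching",
    "RepeatedMatchingResults",
    "summarize",
    "sensitivity_successful_only",
    "run_scenario",
    "run_grid",
]

#: Quantile rule used for the median/IQR summaries (numpy's default linear
#: interpolation between order statistics, as in R's default type 7).
QUANTILE_CONVENTION = "linear"

#: Column order of the per-repetition results table.
REPETITION_COLUMNS = (
    "seed", "n_pairs", "or_hat", "ci_low", "ci_high",
    "defined", "significant_low", "significant_high", "max_smd", "successful",
)

_MOD31 = 2**31


def _rep_seed(base_seed: int, r: int) -> int:
    """Seed of repetition ``r`` (0-based): base + 1 + r, kept below 2^31."""
    return (int(base_seed) + 1 + r) % _MOD31


@dataclass
class ReplicationSummary:
    """One summary row: the distribution of ORs across matching repetitions."""

    scenario: str
    algorithm: str
    caliper_multiplier: float
    reps: int
    median_or: float
    iqr_low: float
    iqr_high: float
    range_low: float
    range_high: float
    crude_or: float
    pct_sig_low: float
    pct_sig_high: float
    mean_matched_subjects: float
    pct_unsuccessful: float
    n_undefined: int
    valid: bool = True

    @property
    def iqr_width(self) -> float:
        return self.iqr_high - self.iqr_low


def summarize(
    repetitions: pd.DataFrame,
    *,
    scenario: str = "",
    algorithm: str = "",
    caliper_multiplier: float = np.nan,
    crude: float = np.nan,
) -> ReplicationSummary:
    """Condense a per-repetition table into a :class:`ReplicationSummary`.

    Median/IQR/range are taken over the repetitions with a defined OR;
    percentages (significance, unsuccessful matching) use all repetitions as
    denominator; the mean matched-subject count is twice the mean pair count.
    """
    if len(repetitions) == 0:
        raise ValueError("cannot summarise zero repetitions")
    reps = len(repetitions)
    defined = repetitions["defined"].to_numpy(dtype=bool)
    n_undefined = int(reps - defined.sum())
    ors = repetitions.loc[defined, "or_hat"].to_numpy(dtype=float)
    if ors.size:
        q25, q50, q75 = np.quantile(ors, [0.25, 0.5, 0.75], method=QUANTILE_CONVENTION)
        lo, hi = float(ors.min()), float(ors.max())
        valid = True
    else:
        q25 = q50 = q75 = lo = hi = np.nan
        valid = False
    return ReplicationSummary(
        scenario=scenario,
        algorithm=algorithm,
        caliper_multiplier=float(caliper_multiplier),
        reps=reps,
        median_or=float(q50), iqr_low=float(q25), iqr_high=float(q75),
        range_low=lo, range_high=hi,
        crude_or=float(crude),
        pct_sig_low=100.0 * float(np.mean(repetitions["significant_low"])),
        pct_sig_high=100.0 * float(np.mean(repetitions["significant_high"])),
        mean_matched_subjects=2.0 * float(np.mean(repetitions["n_pairs"])),
        pct_unsuccessful=100.0 * float(np.mean(~repetitions["successful"].to_numpy(dtype=bool))),
        n_undefined=n_undefined,
        valid=valid,
    )


def sensitivity_successful_only(
    repetitions: pd.DataFrame, **kwargs
) -> ReplicationSummary:
    """Summary restricted to repetitions passing the SMD balance rule."""
    subset = repetitions[repetitions["successful"].astype(bool)]
    if len(subset) == 0:
        out = summarize(repetitions, **kwargs)
        out.valid = False
        return out
    return summarize(subset.reset_index(drop=True), **kwargs)


class RepeatedMatching:
    """Model: repeated greedy PS matching of one cohort.

    Parameters
    ----------
    cohort : Cohort
        The (usually simulated) cohort to be matched.
    algorithm : {"caliper_random", "nn_caliper"}
        Greedy matching variant.
    caliper_multiplier : float
        Caliper width as a multiple of the propensity-score SD (0.2 / 0.01
        in the study).
    scale : {"probability", "logit"}
        Scale on which scores are compared; the study matches on the
        probability scale.
    propensity_fit : PropensityFit, optional
        Reuse an existing fit (e.g. to compare algorithms on the identical
        scores); fitted from the cohort when omitted.
    """

    def __init__(
        self,
        cohort: Cohort,
        algorithm: str = "caliper_random",
        caliper_multiplier: float = 0.2,
        *,
        scale: str = "probability",
        propensity_fit: PropensityFit | None = None,
        scenario_label: str = "",
    ) -> None:
        if algorithm not in MATCHERS:
            raise ValueError(f"unknown matching algorithm {algorithm!r}")
        self.cohort = cohort
        self.algorithm = algorithm
        self.caliper_multiplier = float(caliper_multiplier)
        self.scale = scale
        self.scenario_label = scenario_label
        self.propensity_fit = (
            propensity_fit if propensity_fit is not None else fit_propensity(cohort)
        )

    @classmethod
    def from_scenario(cls, scenario: Scenario, **kwargs) -> "RepeatedMatching":
        return cls(simulate_cohort(scenario), scenario_label=scenario.label, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RepeatedMatching":
        return cls(Cohort.from_frame(df), **kwargs)

    def fit(self, reps: int = 1000, base_seed: int = 0) -> "RepeatedMatchingResults":
        """Run ``reps`` matching repetitions, seeds ``base_seed + 1 + r``."""
        if reps < 1:
            raise ValueError("reps must be >= 1")
        matcher = MATCHERS[self.algorithm]
        rows = []
        for r in range(reps):
            seed = _rep_seed(base_seed, r)
            config = MatchConfig(
                algorithm=self.algorithm,
                caliper_multiplier=self.caliper_multiplier,
                seed=seed,
                scale=self.scale,
            )
            matched = matcher(self.propensity_fit, self.cohort, config)
            if matched.n_pairs == 0:
                rows.append((seed, 0, np.nan, np.nan, np.nan,
                             False, False, False, np.nan, False))
                continue
            est = conditional_or(matched, self.cohort)
            bal = balance(matched, self.cohort)
            rows.append((
                seed, matched.n_pairs, est.or_hat, est.ci_low, est.ci_high,
                est.defined, est.significant_low, est.significant_high,
                bal.max_smd, bal.successful,
            ))
        frame = pd.DataFrame(rows, columns=list(REPETITION_COLUMNS))
        return RepeatedMatchingResults(self, frame, base_seed)


class RepeatedMatchingResults:
    """Results of a repeated-matching fit.

    ``per_repetition`` holds one row per matching repetition; the scalar
    summaries (``median_or``, ``iqr``, ``or_range``, ``pct_sig_low``,
    ``pct_sig_high``, ``mean_matched_subjects``, ``pct_unsuccessful``)
    describe the across-repetition distribution of the OR.
    """

    def __init__(
        self, model: RepeatedMatching, per_repetition: pd.DataFrame, base_seed: int
    ) -> None:
        self.model = model
        self.per_repetition = per_repetition
        self.base_seed = int(base_seed)
        self.crude_or = crude_or(model.cohort)
        self._summary = summarize(
            per_repetition,
            scenario=model.scenario_label,
            algorithm=model.algorithm,
            caliper_multiplier=model.caliper_multiplier,
            crude=self.crude_or,
        )

    # scalar accessors -----------------------------------------------------
    @property
    def reps(self) -> int:
        return self._summary.reps

    @property
    def median_or(self) -> float:
        return self._summary.median_or

    @property
    def iqr(self) -> tuple[float, float]:
        return (self._summary.iqr_low, self._summary.iqr_high)

    @property
    def iqr_width(self) -> float:
        return self._summary.iqr_width

    @property
    def or_range(self) -> tuple[float, float]:
        return (self._summary.range_low, self._summary.range_high)

    @property
    def pct_sig_low(self) -> float:
        return self._summary.pct_sig_low

    @property
    def pct_sig_high(self) -> float:
        return self._summary.pct_sig_high

    @property
    def mean_matched_subjects(self) -> float:
        return self._summary.mean_matched_subjects

    @property
    def pct_unsuccessful(self) -> float:
        return self._summary.pct_unsuccessful

    @property
    def n_undefined(self) -> int:
        return self._summary.n_undefined

    @property
    def valid(self) -> bool:
        return self._summary.valid

    def replication_summary(self) -> ReplicationSummary:
        return self._summary

    def successful_only(self) -> ReplicationSummary:
        """Sensitivity analysis excluding unsuccessfully matched sets."""
        return sensitivity_successful_only(
            self.per_repetition,
            scenario=self.model.scenario_label,
            algorithm=self.model.algorithm,
            caliper_multiplier=self.model.caliper_multiplier,
            crude=self.crude_or,
        )

    def summary(self) -> SimpleTable:
        """Human-readable summary table of the across-repetition spread."""
        s = self._summary
        rows = [
            ("algorithm", s.algorithm),
            ("caliper multiplier", f"{s.caliper_multiplier:g} x SD(ps)"),
            ("repetitions", f"{s.reps}"),
            ("median OR", f"{s.median_or:.3f}"),
            ("IQR of OR", f"({s.iqr_low:.3f}, {s.iqr_high:.3f})"),
            ("full range of OR", f"({s.range_low:.3f}, {s.range_high:.3f})"),
            ("crude (unadjusted) OR", f"{s.crude_or:.3f}"),
            ("% significant low risk", f"{s.pct_sig_low:.1f}%"),
            ("% significant high risk", f"{s.pct_sig_high:.1f}%"),
            ("mean matched subjects", f"{s.mean_matched_subjects:.0f}"),
            ("% unsuccessful matches", f"{s.pct_unsuccessful:.1f}%"),
            ("undefined ORs", f"{s.n_undefined}"),
        ]
        return SimpleTable(
            [[v] for _, v in rows],
            headers=["value"],
            stubs=[k for k, _ in rows],
            title="Repeated greedy PS matching",
        )


def run_scenario(
    scenario: Scenario,
    *,
    reps: int = 1000,
    base_seed: int = 0,
    algorithms: Sequence[str] = ("caliper_random", "nn_caliper"),
    caliper_multipliers: Sequence[float] = (0.2, 0.01),
    scale: str = "probability",
) -> tuple[list[ReplicationSummary], dict[tuple[str, float], pd.DataFrame]]:
    """Run every requested algorithm/caliper on one scenario's cohort.

    A single cohort is simulated (seeded by the scenario) and a single
    propensity fit is shared, so algorithm and caliper comparisons are
    within-cohort.  Repetition ``r`` always uses seed ``base_seed + 1 + r``,
    for every algorithm, making runs individually reproducible.
    """
    cohort = simulate_cohort(scenario)
    ps_fit = fit_propensity(cohort)
    summaries: list[ReplicationSummary] = []
    frames: dict[tuple[str, float], pd.DataFrame] = {}
    for multiplier in caliper_multipliers:
        for algorithm in algorithms:
            model = RepeatedMatching(
                cohort, algorithm, multiplier,
                scale=scale, propensity_fit=ps_fit,
                scenario_label=scenario.label,
            )
            res = model.fit(reps=reps, base_seed=base_seed)
            summaries.append(res.replication_summary())
            frames[(algorithm, multiplier)] = res.per_repetition
    return summaries, frames


def run_grid(
    scenarios: Iterable[Scenario],
    *,
    reps: int = 1000,
    base_seed: int = 0,
    algorithms: Sequence[str] = ("caliper_random", "nn_caliper"),
    caliper_multipliers: Sequence[float] = (0.2, 0.01),
    progress=None,
    include_sensitivity: bool = False,
) -> pd.DataFrame:
    """Run the whole scenario grid, one summary row per
    (scenario, caliper multiplier, algorithm).

    Per-scenario failures are recorded in an ``error`` column and the grid
    continues.  ``progress`` may be a callable receiving a status string.
    """
    rows = []
    for i, scenario in enumerate(scenarios):
        if progress is not None:
            progress(f"scenario {i + 1}: {scenario.label}")
        try:
            summaries, frames = run_scenario(
                scenario, reps=reps, base_seed=base_seed,
                algorithms=algorithms, caliper_multipliers=caliper_multipliers,
            )
        except Exception as exc:  # noqa: BLE001 - grid must keep going
            rows.append({"scenario": scenario.label, "error": str(exc)})
            continue
        for s in summaries:
            row = {**s.__dict__, "error": ""}
            rows.append(row)
            if include_sensitivity:
                sens = sensitivity_successful_only(
                    frames[(s.algorithm, s.caliper_multiplier)],
                    scenario=s.scenario, algorithm=s.algorithm,
                    caliper_multiplier=s.caliper_multiplier, crude=s.crude_or,
                )
                rows.append({**sens.__dict__, "error": "",
                             "scenario": sens.scenario + "_successful_only"})
    return pd.DataFrame(rows)
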