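"""Shared fixtures and toy-problem builders."""

from __future__ import annotations

import numpy as np
import pytest

from greedymatch import Cohort, PropensityFit


def make_toy(treated_ps, control_ps, y_treated=None, y_control=None):
    """A cohort + propensity fit with hand-specified scores.

    Treated subjects occupy ids 0..len(treated_ps)-1, controls follow.
    Outcomes default to 0 (matcher tests don't need them).
    """
    treated_ps = np.asarray(treated_ps, dtype=float)
    control_ps = np.asarray(control_ps, dtype=float)
    n = treated_ps.size + control_ps.size
    t = np.concatenate([np.ones(treated_ps.size), np.zeros(control_ps.size)])
    if y_treated is None:
        y_treated = np.zeros(treated_ps.size)
    if y_control is None:
        y_control = np.zeros(control_ps.size)
    y = np.concatenate([np.asarray(y_treated), np.asarray(y_control)])
    ps = np.concatenate([treated_ps, control_ps])
    cohort = Cohort(
        X=np.zeros((n, 1)), t=t, y=y, covariate_names=("x1",),
    )
    sd = float(np.std(ps, ddof=1)) if n > 1 else 0.0
    fit = PropensityFit(
        coefficients=np.zeros(2), ps=ps, sd_ps=sd, converged=True,
    )
    return cohort, fit


@pytest.fixture
def toy():
    return make_toy
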