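"""Behavioral summary statistics of interval reproduction.

Quantifies the central-tendency (regression) effect and response variability
of a session:

* ``slope``/``intercept`` — ordinary least squares of single-trial
  reproductions ``r`` on stimuli ``s``; a slope of 1 means no regression,
  smaller slopes mean stronger regression toward the mean.
* ``CV(r) = E_s[ STD_s(r) / E_r[r|s] ]`` — per-stimulus coefficient of
  variation averaged with equal weight across stimuli (population SD,
  ddof=0).
* ``BIAS(r) = E_s[ E_r[r|s] - s ]`` — mean over stimuli of the mean signed
  reproduction error, in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .synthetic import StimulusGrid, TrialRecord

__all__ = [
    "BehaviorSummary",
    "regression_slope",
    "coefficient_of_variation",
    "bias",
    "summarize",
    "optimal_shrinkage",
]


def _arrays(trials: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([t.stimulus for t in trials], dtype=float)
    r = np.array([t.reproduction for t in trials], dtype=float)
    return s, r


def regression_slope(trials: Sequence[TrialRecord]) -> tuple[float, float]:
    """OLS slope and intercept of reproductions on stimuli (single trials)."""
    s, r = _arrays(trials)
    if len(np.unique(s)) < 2:
        raise ValueError("regression requires at least two distinct stimulus values")
    fit = stats.linregress(s, r)
    return float(fit.slope), float(fit.intercept)


def coefficient_of_variation(trials: Sequence[TrialRecord]) -> float:
    """Per-stimulus SD over per-stimulus mean, averaged across stimuli."""
    s, r = _arrays(trials)
    cvs = []
    for stim in np.unique(s):
        resp = r[s == stim]
        mean = resp.mean()
        if mean == 0:
            raise ValueError(f"mean reproduction is zero for stimulus {stim}")
        cvs.append(resp.std(ddof=0) / mean)
    return float(np.mean(cvs))


def bias(trials: Sequence[TrialRecord]) -> float:
    """Mean over stimuli of (mean reproduction - stimulus), seconds."""
    s, r = _arrays(trials)
    return float(np.mean([r[s == stim].mean() - stim for stim in np.unique(s)]))


@dataclass(frozen=True)
class BehaviorSummary:
    slope: float
    intercept: float
    cv: float
    bias: float
    mean_tolerance: float
    reward_rate: float


def summarize(trials: Sequence[TrialRecord]) -> BehaviorSummary:
    """Full per-session behavioral summary."""
    slope, intercept = regression_slope(trials)
    return BehaviorSummary(
        slope=slope,
        intercept=intercept,
        cv=coefficient_of_variation(trials),
        bias=bias(trials),
        mean_tolerance=float(np.mean([t.tolerance for t in trials])),
        reward_rate=float(np.mean([t.reward for t in trials])),
    )


def optimal_shrinkage(w_m: float, grid: StimulusGrid) -> float:
    """Shrinkage weight minimizing expected squared error under the observer.

    For a measurement ``m = s(1 + w_m z)`` and a prior with the grid's mean
    and variance, the squared-error-optimal weight on the measurement is
    ``1 / (1 + w_m^2 * mean(grid)^2 / var(grid))`` — noisier measurements get
    shrunk harder toward the prior mean, coupling response variability to the
    strength of the regression effect.
    """
    durations = np.asarray(grid.durations, dtype=float)
    var = durations.var(ddof=0)
    if var == 0:
        return 0.0
    return float(1.0 / (1.0 + w_m**2 * durations.mean() ** 2 / var))
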