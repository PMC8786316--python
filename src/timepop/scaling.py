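"""Temporal scaling of firing-rate profiles across stimulus durations.

For each unit and stimulus the center of mass (COM) of the SDF is computed;
dividing a unit's COM at each stimulus by its COM at the reference stimulus
(5.25 s, the grid mean) yields scaling indices. A perfectly scaling unit —
one whose rate depends only on the fraction of elapsed interval t/s — has
index s/5.25, i.e. between 3.0/5.25 ~ 0.57 and 7.5/5.25 ~ 1.43 on the
default grid, while an absolute-clock unit keeps index ~ 1. A
shuffled-identity control (unit labels permuted independently per stimulus)
and subsampled two-sample Kolmogorov-Smirnov tests quantify whether observed
indices reflect genuine duration-dependent modulation.

COMs are computed on traces shifted by their minimum so weights are
non-negative; z-scored inputs and their controls get the identical treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sdf import SDFTensor

__all__ = [
    "center_of_mass",
    "com_table",
    "scaling_indices",
    "shuffled_indices",
    "bootstrap_ks_scaling",
    "ScalingResult",
]


def center_of_mass(trace, duration: float, shift: bool = True) -> float:
    """Rate-weighted mean time (seconds) of a trace on [0, duration].

    Bin centers are ``(i + 0.5) * duration / n``. With ``shift=True`` the
    trace is shifted by its minimum so weights are non-negative (required for
    z-scored traces). All-zero weights give NaN.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    w = np.asarray(trace, dtype=float)
    if shift:
        w = w - w.min()
    if np.any(w < 0):
        raise ValueError("trace must be non-negative (or use shift=True)")
    total = w.sum()
    if total <= 0:
        return float("nan")
    n = len(w)
    t = (np.arange(n) + 0.5) * duration / n
    return float(np.dot(t, w) / total)


def com_table(sdf: SDFTensor, shift: bool = True) -> np.ndarray:
    """(units, stimuli) COMs in seconds on each stimulus' real duration."""
    v = sdf.values
    out = np.empty((sdf.n_units, sdf.n_stimuli))
    for u in range(sdf.n_units):
        for j in range(sdf.n_stimuli):
            out[u, j] = center_of_mass(v[u, j], sdf.durations[j], shift=shift)
    return out


def _reference_index(stimuli: np.ndarray, reference: float) -> int:
    j = int(np.argmin(np.abs(stimuli - reference)))
    if not np.isclose(stimuli[j], reference):
        raise ValueError(f"reference stimulus {reference} not in grid {stimuli}")
    return j


def scaling_indices(
    com_seconds: np.ndarray, stimuli, reference: float = 5.25
) -> np.ndarray:
    """Per-unit, per-stimulus COM ratios relative to the reference stimulus.

    Units with an undefined (NaN or zero) reference COM are excluded (their
    row is NaN). The index at the reference stimulus is exactly 1.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    j_ref = _reference_index(stimuli, reference)
    ref = com_seconds[:, j_ref]
    out = np.full_like(com_seconds, np.nan, dtype=float)
    ok = np.isfinite(ref) & (ref > 0)
    out[ok] = com_seconds[ok] / ref[ok, None]
    return out


def shuffled_indices(
    com_seconds: np.ndarray, stimuli, reference: float = 5.25, seed=0
) -> np.ndarray:
    """Scaling indices after permuting unit identities independently per
    stimulus (the shuffled-identity control)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shuffled = com_seconds.copy()
    for j in range(shuffled.shape[1]):
        shuffled[:, j] = shuffled[rng.permutation(shuffled.shape[0]), j]
    return scaling_indices(shuffled, stimuli, reference)


@dataclass
class ScalingResult:
    """Subsampled KS comparison of two scaling-index samples."""

    pvalues: np.ndarray
    fraction_significant: float
    alpha: float
    frac: float


def bootstrap_ks_scaling(
    indices_data,
    indices_control,
    frac: float = 0.1,
    runs: int = 10000,
    seed=0,
    alpha: float = 0.05,
    method: str = "auto",
) -> ScalingResult:
    """Repeated two-sample KS tests on random ``frac`` subsamples.

    Each run subsamples ``frac`` of each sample without replacement and
    records the two-sample KS p-value; the summary is the fraction of runs
    with p < ``alpha``. NaNs are dropped beforehand. ``method`` is passed to
    the KS test ('exact' avoids the conservative asymptotic p-value at
    moderate subsample sizes).
    """
    x = np.asarray(indices_data, dtype=float).ravel()
    y = np.asarray(indices_control, dtype=float).ravel()
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both index samples must be non-empty")
    n_x = int(np.floor(frac * len(x)))
    n_y = int(np.floor(frac * len(y)))
    if n_x < 5 or n_y < 5:
        raise ValueError("subsample smaller than 5; increase frac or sample size")
    rng = np.random.default_rng(seed)
    pvals = np.empty(runs)
    for i in range(runs):
        xs = rng.choice(x, n_x, replace=False)
        ys = rng.choice(y, n_y, replace=False)
        pvals[i] = stats.ks_2samp(xs, ys, method=method).pvalue
    frac_sig = float(np.mean(pvals < alpha)) if runs else float("nan")
    return ScalingResult(pvalues=pvals, fraction_significant=frac_sig, alpha=alpha, frac=frac)
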