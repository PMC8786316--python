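"""Running-speed response functions and the speed-modulation index.

The speed response function counts spikes emitted while the animal moved at
a given speed (5 cm/s bins between 10 and 100 cm/s) and divides by the time
spent at that speed. Significance of speed modulation comes from a shuffle
control: spike times are circularly shifted by a random offset (preserving
ISI structure), the response function recomputed, and — for robustness —
the shuffle with the largest across-bin rate variance of 10 repeats is kept;
a one-sided Levene test then asks whether the true response function's
variance exceeds the control's. The modulation index contrasts the average
rate in the lowest and highest 10% of occupied speed bins,
``(r90 - r10) / (r90 + r10)``, and lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SpeedResponse", "speed_response_function", "modulation_index"]


@dataclass
class SpeedResponse:
    """Binned firing rate as a function of running speed."""

    edges: np.ndarray  # bin edges, cm/s
    rates: np.ndarray  # Hz; NaN where occupancy is zero
    occupancy: np.ndarray  # seconds per bin
    variance: float  # across-bin rate variance (occupied bins)
    shuffle_variance: float  # largest variance over the shuffles
    p_value: float  # one-sided Levene p (var_true > var_shuffle)
    significant: bool


def _binned_rates(
    spike_speeds: np.ndarray, occupancy: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    counts, _ = np.histogram(spike_speeds, bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = counts / occupancy
    rates[occupancy <= 0] = np.nan
    return rates


def speed_response_function(
    spike_times: np.ndarray,
    speed: np.ndarray,
    dt: float,
    bin_width: float = 5.0,
    v_min: float = 10.0,
    v_max: float = 100.0,
    n_shuffles: int = 10,
    seed=0,
    alpha: float = 0.05,
) -> SpeedResponse:
    """Speed response function with shuffle-based significance.

    ``speed`` samples the running speed (cm/s) on a regular ``dt`` grid
    covering all spike times. Raises if the animal spent less than 1 s in
    the analyzed speed range.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    speed = np.asarray(speed, dtype=float)
    duration = len(speed) * dt
    if len(spike_times) and spike_times[-1] > duration + dt:
        raise ValueError("speed trace does not cover the spike times")
    edges = np.arange(v_min, v_max + bin_width / 2, bin_width)
    sample_counts, _ = np.histogram(speed, bins=edges)
    occupancy = sample_counts * dt
    if occupancy.sum() < 1.0:
        raise ValueError("less than 1 s of occupancy in the analyzed speed range")

    def speeds_at(times: np.ndarray) -> np.ndarray:
        idx = np.minimum((times / dt).astype(int), len(speed) - 1)
        return speed[idx]

    rates = _binned_rates(speeds_at(spike_times), occupancy, edges)
    occupied = occupancy > 0
    variance = float(np.nanvar(rates[occupied])) if occupied.any() else float("nan")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best_var = -np.inf
    best_rates = None
    for _ in range(n_shuffles):
        offset = rng.uniform(0.0, duration)
        shifted = np.sort((spike_times + offset) % duration)
        shuf_rates = _binned_rates(speeds_at(shifted), occupancy, edges)
        shuf_var = float(np.nanvar(shuf_rates[occupied])) if occupied.any() else np.nan
        if shuf_var > best_var:
            best_var = shuf_var
            best_rates = shuf_rates
    true_sample = rates[occupied & np.isfinite(rates)]
    shuf_sample = best_rates[occupied & np.isfinite(best_rates)]
    if len(true_sample) >= 2 and len(shuf_sample) >= 2 and (
        np.ptp(true_sample) > 0 or np.ptp(shuf_sample) > 0
    ):
        p_two = float(stats.levene(true_sample, shuf_sample).pvalue)
    else:
        p_two = 1.0
    # one-sided: only variances larger than the shuffle control count
    if variance > best_var:
        p_one = p_two / 2.0
    else:
        p_one = 1.0 - p_two / 2.0
    return SpeedResponse(
        edges=edges,
        rates=rates,
        occupancy=occupancy,
        variance=variance,
        shuffle_variance=best_var,
        p_value=p_one,
        significant=bool(p_one < alpha),
    )


def modulation_index(response: SpeedResponse) -> float:
    """(r90 - r10) / (r90 + r10) over the speed axis of the response.

    ``r10``/``r90`` average the rates of the lowest/highest 10% of occupied
    speed bins (at least one bin each). NaN when both rates are zero.
    """
    occupied = np.flatnonzero((response.occupancy > 0) & np.isfinite(response.rates))
    if len(occupied) == 0:
        return float("nan")
    k = max(1, int(round(0.1 * len(occupied))))
    r10 = float(response.rates[occupied[:k]].mean())
    r90 = float(response.rates[occupied[-k:]].mean())
    if r10 + r90 == 0:
        return float("nan")
    return (r90 - r10) / (r90 + r10)
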