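"""Spike density functions (SDFs) and their control surrogates.

SDFs are trial-averaged firing rates from causal (right-aligned) 100 ms count
bins, computed per unit and per stimulus within one task phase. Because
reproduction durations vary across trials of the same stimulus, reproduction
spikes are first linearly warped so each trial maps onto the stimulus' mean
reproduced duration. Traces are then resampled to a common number of bins
(time normalization) and z-scored per unit over the concatenation of that
unit's stimulus traces within the phase, preserving across-stimulus amplitude
ordering for the downstream stimulus components.

Two surrogate controls mirror the analysis' null models: ``shuffled`` permutes
unit identities independently per stimulus; ``noise`` permutes each trace's
bins over time, destroying temporal structure while keeping the marginal
value distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import SpikeData

__all__ = [
    "SDFTensor",
    "compute_sdf",
    "warp_reproduction_trials",
    "normalize_and_zscore",
    "control_sdfs",
    "smooth_half_gaussian",
    "from_rates",
    "write_sdf_hdf5",
    "read_sdf_hdf5",
]


@dataclass
class SDFTensor:
    """Per-unit, per-stimulus firing-rate traces for one task phase.

    ``traces[j]`` is a (units, n_bins_j) array for stimulus ``stimuli[j]``;
    after time normalization all stimuli share the same bin count and
    ``values`` stacks them into a (units, stimuli, bins) array.
    ``durations[j]`` is the real-time extent of stimulus ``j``'s traces: the
    stimulus duration in the measurement phase, the mean reproduced duration
    in the reproduction phase.
    """

    traces: list[np.ndarray]
    stimuli: np.ndarray
    durations: np.ndarray
    phase: str
    alignment: str
    bin_width: float | None
    zscored: bool = False

    def __post_init__(self):
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)

    @property
    def n_units(self) -> int:
        return self.traces[0].shape[0]

    @property
    def n_stimuli(self) -> int:
        return len(self.traces)

    @property
    def is_normalized(self) -> bool:
        return len({tr.shape[1] for tr in self.traces}) == 1

    @property
    def n_bins(self) -> int:
        if not self.is_normalized:
            raise ValueError("tensor is ragged; time-normalize first")
        return self.traces[0].shape[1]

    @property
    def values(self) -> np.ndarray:
        """(units, stimuli, bins) array; requires equal bin counts."""
        if not self.is_normalized:
            raise ValueError("tensor is ragged; time-normalize first")
        return np.stack(self.traces, axis=1)

    def with_values(self, values: np.ndarray, **changes) -> "SDFTensor":
        traces = [values[:, j, :] for j in range(values.shape[1])]
        return replace(self, traces=traces, **changes)


def _bin_counts(spikes: np.ndarray, start: float, n_bins: int, width: float) -> np.ndarray:
    """Counts in right-aligned bins (start + j*w, start + (j+1)*w]."""
    edges = start + width * np.arange(n_bins + 1)
    idx = np.searchsorted(spikes, edges, side="right")
    return np.diff(idx).astype(float)


def compute_sdf(
    spikes: SpikeData,
    phase: str,
    alignment: str = "phase_begin",
    bin_width: float = 0.1,
) -> SDFTensor:
    """Trial-averaged SDFs in causal ``bin_width`` bins, per unit and stimulus.

    Bins are right aligned (each bin looks into the past), laid out from the
    alignment point; bins partially outside the phase at the non-aligned edge
    are dropped. For the reproduction phase run
    :func:`warp_reproduction_trials` first so all trials of a stimulus share
    the mean reproduced duration. Trials shorter than one bin are skipped
    with a warning.
    """
    if alignment not in ("phase_begin", "phase_end"):
        raise ValueError("alignment must be 'phase_begin' or 'phase_end'")
    stimuli = np.unique(spikes.stimuli)
    traces = []
    durations = np.empty(len(stimuli))
    for j, stim in enumerate(stimuli):
        trial_idx = np.flatnonzero(spikes.stimuli == stim)
        phase_durs = np.array(
            [np.subtract(*spikes.phase_window(i, phase)[::-1]) for i in trial_idx]
        )
        duration = float(phase_durs.mean())
        n_bins = int(np.floor(duration / bin_width + 1e-9))
        if n_bins < 1:
            raise ValueError("phase shorter than one bin for all trials")
        durations[j] = duration
        arr = np.zeros((spikes.n_units, n_bins))
        used = 0
        for i, d in zip(trial_idx, phase_durs):
            if d < bin_width:
                warnings.warn(f"trial {i} shorter than one bin; skipped")
                continue
            t_begin, t_end = spikes.phase_window(i, phase)
            start = t_begin if alignment == "phase_begin" else t_end - n_bins * bin_width
            for u in range(spikes.n_units):
                arr[u] += _bin_counts(spikes.trains[u][i], start, n_bins, bin_width)
            used += 1
        if used == 0:
            raise ValueError(f"no usable trials for stimulus {stim}")
        traces.append(arr / (used * bin_width))
    return SDFTensor(
        traces=traces,
        stimuli=stimuli,
        durations=durations,
        phase=phase,
        alignment=alignment,
        bin_width=bin_width,
        zscored=False,
    )


def warp_reproduction_trials(spikes: SpikeData) -> SpikeData:
    """Linearly rescale each trial's reproduction phase to the per-stimulus
    mean reproduced duration (spike counts are preserved)."""
    new_trains = [[train.copy() for train in unit] for unit in spikes.trains]
    new_phases = spikes.phases.copy()
    for stim in np.unique(spikes.stimuli):
        idx = np.flatnonzero(spikes.stimuli == stim)
        mean_r = float(np.mean([spikes.phases[i, 3] - spikes.phases[i, 2] for i in idx]))
        for i in idx:
            t2, t3 = spikes.phases[i, 2], spikes.phases[i, 3]
            factor = mean_r / (t3 - t2)
            for u in range(spikes.n_units):
                train = new_trains[u][i]
                in_phase = (train >= t2) & (train <= t3)
                train[in_phase] = t2 + (train[in_phase] - t2) * factor
                after = train > t3
                train[after] = train[after] + (mean_r - (t3 - t2))
                new_trains[u][i] = np.sort(train)
            new_phases[i, 3] = t2 + mean_r
    return SpikeData(
        trains=new_trains,
        phases=new_phases,
        stimuli=spikes.stimuli.copy(),
        reproductions=spikes.reproductions.copy(),
    )


def _resample(trace: np.ndarray, n_bins: int) -> np.ndarray:
    m = trace.shape[-1]
    x_old = (np.arange(m) + 0.5) / m
    x_new = (np.arange(n_bins) + 0.5) / n_bins
    return np.interp(x_new, x_old, trace)


def normalize_and_zscore(sdf: SDFTensor, n_bins: int = 40, zscore: bool = True) -> SDFTensor:
    """Resample every trace to ``n_bins`` samples, then z-score per unit.

    z-scoring is per unit over the concatenation of all its stimulus traces
    within the phase; a constant unit maps to all zeros.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.empty((sdf.n_units, sdf.n_stimuli, n_bins))
    for j, tr in enumerate(sdf.traces):
        for u in range(sdf.n_units):
            values[u, j] = _resample(tr[u], n_bins)
    if zscore:
        flat = values.reshape(sdf.n_units, -1)
        mean = flat.mean(axis=1, keepdims=True)
        sd = flat.std(axis=1, ddof=0, keepdims=True)
        sd_safe = np.where(sd < 1e-12, 1.0, sd)
        flat = (flat - mean) / sd_safe
        flat[np.squeeze(sd < 1e-12, axis=1)] = 0.0
        values = flat.reshape(values.shape)
    out = sdf.with_values(values, bin_width=None, zscored=zscore)
    return out


def control_sdfs(sdf: SDFTensor, mode: str, seed) -> SDFTensor:
    """Surrogate tensors: ``shuffled`` permutes unit identities per stimulus;
    ``noise`` permutes each trace's bins over time."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = sdf.values.copy()
    if mode == "shuffled":
        for j in range(values.shape[1]):
            values[:, j, :] = values[rng.permutation(values.shape[0]), j, :]
    elif mode == "noise":
        for u in range(values.shape[0]):
            for j in range(values.shape[1]):
                values[u, j, :] = values[u, j, rng.permutation(values.shape[2])]
    else:
        raise ValueError("mode must be 'shuffled' or 'noise'")
    return sdf.with_values(values)


def half_gaussian_kernel(sd_bins: float = 3.0) -> np.ndarray:
    """Causal half-Gaussian kernel (support at non-positive lags), sum 1."""
    lags = np.arange(int(np.ceil(4 * sd_bins)) + 1)
    k = np.exp(-0.5 * (lags / sd_bins) ** 2)
    return k / k.sum()


def smooth_half_gaussian(sdf: SDFTensor, sd_bins: float = 3.0) -> SDFTensor:
    """Causal half-Gaussian smoothing (visualization only).

    Each output bin is a weighted mean of the current and past bins; at the
    left edge the kernel is renormalized over the available past so a
    constant input stays constant.
    """
    kernel = half_gaussian_kernel(sd_bins)
    L = len(kernel)
    traces = []
    for tr in sdf.traces:
        n = tr.shape[1]
        out = np.zeros_like(tr)
        norm = np.zeros(n)
        for lag, w in enumerate(kernel):
            out[:, lag:] += w * tr[:, : n - lag if lag else n]
            norm[lag:] += w
        traces.append(out / norm)
    return replace(sdf, traces=traces)


def from_rates(
    values: np.ndarray,
    durations,
    phase: str = "measurement",
    zscored: bool = False,
) -> SDFTensor:
    """Wrap a (units, stimuli, bins) rate array as a normalized SDFTensor."""
    values = np.asarray(values, dtype=float)
    durations = np.asarray(durations, dtype=float)
    traces = [values[:, j, :] for j in range(values.shape[1])]
    return SDFTensor(
        traces=traces,
        stimuli=durations.copy(),
        durations=durations,
        phase=phase,
        alignment="phase_begin",
        bin_width=None,
        zscored=zscored,
    )


def write_sdf_hdf5(path, tensors: dict[str, SDFTensor]) -> None:
    """Serialize normalized SDF tensors, one dataset per phase."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, sdf in tensors.items():
            d = f.create_dataset(name, data=sdf.values)
            d.attrs["stimuli"] = sdf.stimuli
            d.attrs["durations"] = sdf.durations
            d.attrs["phase"] = sdf.phase
            d.attrs["alignment"] = sdf.alignment
            d.attrs["n_bins"] = sdf.n_bins
            d.attrs["zscored"] = sdf.zscored
            d.attrs["bin_width"] = -1.0 if sdf.bin_width is None else sdf.bin_width


def read_sdf_hdf5(path) -> dict[str, SDFTensor]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            d = f[name]
            values = d[...]
            bw = float(d.attrs["bin_width"])
            out[name] = from_rates(
                values, d.attrs["durations"], phase=str(d.attrs["phase"])
            )
            out[name].stimuli = np.asarray(d.attrs["stimuli"], dtype=float)
            out[name].alignment = str(d.attrs["alignment"])
            out[name].zscored = bool(d.attrs["zscored"])
            out[name].bin_width = None if bw < 0 else bw
    return out
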