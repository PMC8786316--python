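"""Synthetic interval-reproduction sessions.

This module generates behavioral trials and spike trains with the statistical
structure the downstream analyses assume:

* a discrete uniform stimulus grid of seven durations between 3 and 7.5 s,
* reproductions from a shrinkage observer (central tendency: regression slope
  below 1; scalar variability: SD proportional to the stimulus),
* an adaptive reward tolerance that narrows by 3 percentage points after a
  rewarded trial and widens by 3 otherwise,
* spike trains drawn from stereotype firing-rate profiles (linear increasing,
  ramp-to-threshold up/down, phasic absolute/relative, stimulus-tuned
  constant, unrelated noise) by inhomogeneous-Poisson thinning, with optional
  additive rate noise and running-speed modulation.

The observer is a minimal generative stand-in for central tendency: the
internal measurement ``m = s*(1 + w_m*z)`` is shrunk toward a prior mean,
``center = lam*m + (1-lam)*mu``, and the reproduction adds multiplicative
production noise with SD ``w_p*center``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "StimulusGrid",
    "DEFAULT_GRID",
    "ObserverParams",
    "StereotypeParams",
    "TrialRecord",
    "SpikeData",
    "SessionConfig",
    "STEREOTYPE_KINDS",
    "sample_stimuli",
    "simulate_observer_trial",
    "update_feedback",
    "stereotype_rate",
    "generate_spike_train",
    "make_population",
    "generate_session",
    "rate_tensor",
    "write_session_hdf5",
    "read_session_hdf5",
    "write_session_csv",
    "read_session_csv",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# behavioral task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusGrid:
    """Discrete uniform grid of stimulus durations (seconds)."""

    durations: tuple[float, ...]

    def __post_init__(self):
        durations = tuple(float(d) for d in self.durations)
        if len(durations) == 0:
            raise ValueError("stimulus grid must contain at least one duration")
        if any(d <= 0 for d in durations):
            raise ValueError("stimulus durations must be positive")
        diffs = np.diff(durations)
        if len(durations) > 1:
            if np.any(diffs <= 0):
                raise ValueError("stimulus grid must be strictly increasing")
            if not np.allclose(diffs, diffs[0]):
                raise ValueError("stimulus grid must be uniformly spaced")
        object.__setattr__(self, "durations", durations)

    @property
    def spacing(self) -> float:
        if len(self.durations) < 2:
            return 0.0
        return self.durations[1] - self.durations[0]

    @property
    def mean(self) -> float:
        return float(np.mean(self.durations))

    @property
    def range(self) -> float:
        return self.durations[-1] - self.durations[0]


#: The seven-duration grid used throughout: 3, 3.75, ..., 7.5 s.
DEFAULT_GRID = StimulusGrid((3.0, 3.75, 4.5, 5.25, 6.0, 6.75, 7.5))


@dataclass(frozen=True)
class ObserverParams:
    """Shrinkage observer with multiplicative measurement/production noise.

    Parameters
    ----------
    shrinkage:
        Weight ``lam`` in [0, 1] on the (noisy) measurement; ``1 - lam`` goes
        to the prior mean. ``lam = 1`` is a veridical observer, ``lam = 0``
        always reproduces the prior mean.
    w_m, w_p:
        Weber fractions of measurement and production noise (dimensionless,
        >= 0); both noises are multiplicative, producing scalar variability.
    prior_mean:
        Prior mean ``mu`` in seconds; normally the mean of the stimulus grid.
    """

    shrinkage: float = 0.7
    w_m: float = 0.1
    w_p: float = 0.1
    prior_mean: float = DEFAULT_GRID.mean

    def __post_init__(self):
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        if self.w_m < 0 or self.w_p < 0:
            raise ValueError("Weber fractions must be non-negative")
        if self.prior_mean <= 0:
            raise ValueError("prior mean must be positive")


def sample_stimuli(grid: StimulusGrid, n_trials: int, seed) -> np.ndarray:
    """Draw ``n_trials`` stimulus durations uniformly from the grid."""
    if len(grid.durations) == 0:  # pragma: no cover - grid forbids this
        raise ValueError("empty stimulus grid")
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = _as_rng(seed)
    return rng.choice(np.asarray(grid.durations), size=int(n_trials))


def simulate_observer_trial(s: float, params: ObserverParams, seed) -> float:
    """Simulate one reproduction of stimulus ``s`` (seconds)."""
    if s <= 0:
        raise ValueError("stimulus duration must be positive")
    rng = _as_rng(seed)
    z1, z2 = rng.standard_normal(2)
    m = s * (1.0 + params.w_m * z1)
    center = params.shrinkage * m + (1.0 - params.shrinkage) * params.prior_mean
    r = center + params.w_p * center * z2
    return float(max(r, 1e-6))


def update_feedback(r: float, s: float, k: float, step: float = 0.03) -> tuple[bool, float]:
    """Reward decision and next-trial tolerance.

    The reproduction is rewarded iff it falls inside ``[(1-k)s, (1+k)s]``; the
    tolerance then narrows by ``step`` (floored at 0) or widens by ``step``.
    """
    if k < 0:
        raise ValueError("tolerance k must be >= 0")
    in_range = (1.0 - k) * s <= r <= (1.0 + k) * s
    k_next = max(0.0, k - step) if in_range else k + step
    return bool(in_range), float(k_next)


# ---------------------------------------------------------------------------
# stereotype neurons
# ---------------------------------------------------------------------------

STEREOTYPE_KINDS = (
    "linear_increasing",
    "ramp_to_threshold_up",
    "ramp_to_threshold_down",
    "phasic_absolute",
    "phasic_relative",
    "stimulus_constant",
    "unrelated_noise",
)


@dataclass(frozen=True)
class StereotypeParams:
    """Parameters of one stereotype firing-rate profile.

    ``kind`` selects the profile; rates are rectified at 0 Hz.

    * ``linear_increasing`` — ``baseline + slope*t``: same slope for every
      stimulus, so the end-of-interval rate encodes duration.
    * ``ramp_to_threshold_up``/``_down`` — ``baseline + amplitude*t/s`` (or
      its mirror): reaches the same level at the end of every interval, so
      after time normalization the profile is stimulus-invariant.
    * ``phasic_absolute`` — Gaussian bump at a fixed clock time ``peak_time``
      with SD ``peak_width`` seconds.
    * ``phasic_relative`` — Gaussian bump at phase ``phase*s`` with SD
      ``peak_width*s`` (bump scales with the interval).
    * ``stimulus_constant`` — time-constant rate, linearly tuned to stimulus
      duration around ``tuning_center`` over ``tuning_range``.
    * ``unrelated_noise`` — baseline only.
    """

    kind: str = "linear_increasing"
    baseline: float = 1.0
    amplitude: float = 10.0
    slope: float = 2.0
    peak_time: float = 2.0
    phase: float = 0.5
    peak_width: float = 0.5
    noise_sd: float = 0.0
    speed_gain: float = 0.0
    tuning_center: float = DEFAULT_GRID.mean
    tuning_range: float = DEFAULT_GRID.range

    def __post_init__(self):
        if self.kind not in STEREOTYPE_KINDS:
            raise ValueError(f"unknown stereotype kind {self.kind!r}")
        if not 0.0 <= self.phase <= 1.0:
            raise ValueError("relative phase must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("rate-noise SD must be >= 0")


def stereotype_rate(params: StereotypeParams, s: float, t) -> np.ndarray | float:
    """Noiseless firing rate (Hz) of a stereotype at times ``t`` in [0, s]."""
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < -1e-12) or np.any(t_arr > s + 1e-12):
        raise ValueError("t must lie within [0, s]")
    k = params.kind
    if k == "linear_increasing":
        rate = params.baseline + params.slope * t_arr
    elif k == "ramp_to_threshold_up":
        rate = params.baseline + params.amplitude * t_arr / s
    elif k == "ramp_to_threshold_down":
        rate = params.baseline + params.amplitude * (1.0 - t_arr / s)
    elif k == "phasic_absolute":
        rate = params.baseline + params.amplitude * np.exp(
            -0.5 * ((t_arr - params.peak_time) / params.peak_width) ** 2
        )
    elif k == "phasic_relative":
        width = params.peak_width * s
        rate = params.baseline + params.amplitude * np.exp(
            -0.5 * ((t_arr - params.phase * s) / width) ** 2
        )
    elif k == "stimulus_constant":
        tuning = (s - params.tuning_center) / params.tuning_range
        rate = np.full_like(t_arr, params.baseline + params.amplitude * tuning)
    else:  # unrelated_noise
        rate = np.full_like(t_arr, params.baseline)
    rate = np.maximum(rate, 0.0)
    return float(rate[0]) if scalar else rate


def generate_spike_train(
    rate: Callable[[np.ndarray], np.ndarray],
    duration: float,
    seed,
    rate_max: float | None = None,
    probe_dt: float = 0.001,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on [0, duration] by thinning.

    ``rate`` must be a non-negative function of time (Hz); if ``rate_max`` is
    not supplied it is bounded by probing on a fine grid.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rng = _as_rng(seed)
    if duration == 0:
        return np.empty(0)
    if rate_max is None:
        probe_t = np.arange(0.0, duration, probe_dt)
        probe = np.asarray(rate(probe_t), dtype=float)
        if np.any(probe < 0):
            raise ValueError("rate must be non-negative on [0, duration]")
        rate_max = float(probe.max()) * 1.0001 + 1e-12
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration)
    if n == 0:
        return np.empty(0)
    candidates = np.sort(rng.uniform(0.0, duration, n))
    vals = np.asarray(rate(candidates), dtype=float)
    if np.any(vals < 0):
        raise ValueError("rate must be non-negative on [0, duration]")
    if np.any(vals > rate_max * (1 + 1e-9)):
        raise ValueError("rate exceeds supplied rate_max")
    keep = rng.uniform(0.0, rate_max, n) < vals
    return candidates[keep]


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """One behavioral trial."""

    stimulus: float
    reproduction: float
    tolerance: float
    reward: bool
    gain: float = 1.0
    speed: np.ndarray | None = None
    speed_dt: float = 0.05

    def __post_init__(self):
        if self.reproduction <= 0:
            raise ValueError("reproduction must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class SpikeData:
    """Spike timestamps per unit per trial, plus per-trial phase markers.

    ``trains[u][i]`` holds the sorted spike times (seconds from trial start)
    of unit ``u`` in trial ``i``. ``phases[i] = (t0, t1, t2, t3)`` marks
    measurement begin/end and reproduction begin/end with
    ``t0 < t1 <= t2 < t3``.
    """

    trains: list[list[np.ndarray]]
    phases: np.ndarray
    stimuli: np.ndarray
    reproductions: np.ndarray

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.reproductions = np.asarray(self.reproductions, dtype=float)
        t0, t1, t2, t3 = self.phases.T
        if np.any(t0 >= t1) or np.any(t1 > t2) or np.any(t2 >= t3):
            raise ValueError("phase markers must satisfy t0 < t1 <= t2 < t3")

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    def phase_window(self, trial: int, phase: str) -> tuple[float, float]:
        t0, t1, t2, t3 = self.phases[trial]
        if phase == "measurement":
            return float(t0), float(t1)
        if phase == "reproduction":
            return float(t2), float(t3)
        raise ValueError("phase must be 'measurement' or 'reproduction'")


#: Default stereotype mixture for a generated population.
DEFAULT_MIXTURE = {
    "linear_increasing": 0.2,
    "ramp_to_threshold_up": 0.15,
    "ramp_to_threshold_down": 0.1,
    "phasic_absolute": 0.1,
    "phasic_relative": 0.1,
    "stimulus_constant": 0.15,
    "unrelated_noise": 0.2,
}


def make_population(
    n_units: int,
    mixture: dict[str, float] | None = None,
    seed=0,
    noise_sd: float = 0.0,
    speed_gain: float = 0.0,
) -> list[StereotypeParams]:
    """Draw a heterogeneous population of stereotype neurons.

    ``mixture`` maps stereotype kinds to fractions (must sum to 1); unit
    counts per kind use largest-remainder rounding. Baselines, amplitudes,
    slopes and peak positions are drawn from broad uniform ranges so no two
    units are identical.
    """
    mixture = dict(DEFAULT_MIXTURE if mixture is None else mixture)
    for kind in mixture:
        if kind not in STEREOTYPE_KINDS:
            raise ValueError(f"unknown stereotype kind {kind!r}")
    total = sum(mixture.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"stereotype mixture fractions must sum to 1 (got {total})")
    rng = _as_rng(seed)
    kinds = list(mixture)
    ideal = np.array([mixture[k] * n_units for k in kinds])
    counts = np.floor(ideal).astype(int)
    remainder = n_units - counts.sum()
    order = np.argsort(-(ideal - counts))
    counts[order[:remainder]] += 1
    population = []
    for kind, count in zip(kinds, counts):
        for _ in range(count):
            population.append(
                StereotypeParams(
                    kind=kind,
                    baseline=rng.uniform(0.5, 3.0),
                    amplitude=rng.uniform(5.0, 15.0),
                    slope=rng.uniform(0.5, 3.0),
                    peak_time=rng.uniform(0.5, 2.9),
                    phase=rng.uniform(0.1, 0.9),
                    peak_width=rng.uniform(0.3, 0.8),
                    noise_sd=noise_sd,
                    speed_gain=speed_gain,
                )
            )
    return population


@dataclass
class SessionConfig:
    """Configuration of one synthetic session."""

    n_trials: int = 50
    n_units: int = 20
    grid: StimulusGrid = DEFAULT_GRID
    observer: ObserverParams = field(default_factory=ObserverParams)
    k0: float = 0.2
    feedback_step: float = 0.03
    mixture: dict[str, float] | None = None
    gap_range: tuple[float, float] = (1.0, 3.0)
    rate_noise_sd: float = 0.0
    speed_gain: float = 0.0
    speed_mean: float = 40.0
    speed_sd: float = 15.0
    speed_dt: float = 0.05
    gain_range: tuple[float, float] = (0.25, 2.25)
    seed: int = 0


def _speed_trace(rng, duration: float, cfg: SessionConfig) -> np.ndarray:
    n = int(np.ceil(duration / cfg.speed_dt)) + 1
    raw = rng.standard_normal(n)
    smooth = gaussian_filter1d(raw, sigma=max(1.0, 0.5 / cfg.speed_dt))
    # restandardize so smoothing does not shrink the configured variability
    sd = smooth.std()
    if sd > 1e-12:
        smooth = smooth / sd
    return np.maximum(cfg.speed_mean + cfg.speed_sd * smooth, 0.0)


def _trial_rate_array(
    params: StereotypeParams,
    phases: np.ndarray,
    stimulus: float,
    reproduction: float,
    speed: np.ndarray,
    speed_dt: float,
    rng,
    dt: float = 0.01,
) -> np.ndarray:
    """Piecewise-constant rate (Hz) on a dt grid over the whole trial."""
    t0, t1, t2, t3 = phases
    tg = np.arange(0.0, t3, dt)
    rate = np.full(tg.shape, params.baseline, dtype=float)
    meas = (tg >= t0) & (tg < t1)
    rate[meas] = stereotype_rate(params, stimulus, np.minimum(tg[meas] - t0, stimulus))
    repro = (tg >= t2) & (tg < t3)
    rate[repro] = stereotype_rate(
        params, reproduction, np.minimum(tg[repro] - t2, reproduction)
    )
    if params.speed_gain != 0.0:
        idx = np.minimum((tg / speed_dt).astype(int), len(speed) - 1)
        rate = rate + params.speed_gain * speed[idx]
    if params.noise_sd > 0:
        # rate noise is piecewise constant on a 100 ms grid, rectified below
        block = max(1, int(round(0.1 / dt)))
        n_blocks = int(np.ceil(len(tg) / block))
        noise = np.repeat(rng.normal(0.0, params.noise_sd, n_blocks), block)[: len(tg)]
        rate = rate + noise
    return np.maximum(rate, 0.0)


def generate_session(
    config: SessionConfig,
    population: Sequence[StereotypeParams] | None = None,
) -> tuple[list[TrialRecord], SpikeData]:
    """Generate a full session: behavioral trials plus population spikes.

    Deterministic under ``config.seed``. Phase markers per trial are
    ``t0=0, t1=s`` (measurement) and ``t2=t1+gap, t3=t2+r`` (reproduction)
    with a stimulus-independent reaction-time gap drawn uniformly from
    ``config.gap_range``.
    """
    root = np.random.SeedSequence(config.seed)
    s_behav, s_pop, s_speed, s_spikes = [np.random.default_rng(c) for c in root.spawn(4)]
    if population is None:
        population = make_population(
            config.n_units,
            config.mixture,
            seed=s_pop,
            noise_sd=config.rate_noise_sd,
            speed_gain=config.speed_gain,
        )
    population = list(population)
    n_units = len(population)

    stimuli = sample_stimuli(config.grid, config.n_trials, s_behav)
    trials: list[TrialRecord] = []
    phases = np.empty((config.n_trials, 4))
    k = config.k0
    for i, s in enumerate(stimuli):
        r = simulate_observer_trial(float(s), config.observer, s_behav)
        reward, k_next = update_feedback(r, float(s), k, config.feedback_step)
        gap = s_behav.uniform(*config.gap_range)
        gain = s_behav.uniform(*config.gain_range)
        phases[i] = (0.0, s, s + gap, s + gap + r)
        speed = _speed_trace(s_speed, phases[i, 3], config)
        trials.append(
            TrialRecord(
                stimulus=float(s),
                reproduction=r,
                tolerance=k,
                reward=reward,
                gain=float(gain),
                speed=speed,
                speed_dt=config.speed_dt,
            )
        )
        k = k_next

    trains: list[list[np.ndarray]] = []
    for params in population:
        unit_trains = []
        for i, trial in enumerate(trials):
            rate = _trial_rate_array(
                params,
                phases[i],
                trial.stimulus,
                trial.reproduction,
                trial.speed,
                trial.speed_dt,
                s_spikes,
            )
            dt = 0.01
            rate_fn = lambda t, arr=rate: arr[
                np.minimum((np.asarray(t) / dt).astype(int), len(arr) - 1)
            ]
            spikes = generate_spike_train(
                rate_fn, phases[i, 3], s_spikes, rate_max=float(rate.max()) + 1e-9
            )
            unit_trains.append(np.sort(spikes))
        trains.append(unit_trains)

    spikes = SpikeData(
        trains=trains,
        phases=phases,
        stimuli=stimuli.astype(float),
        reproductions=np.array([t.reproduction for t in trials]),
    )
    return trials, spikes


def rate_tensor(
    population: Sequence[StereotypeParams],
    durations: Sequence[float],
    n_bins: int = 40,
    seed=None,
) -> np.ndarray:
    """Noise-free (or rate-noise-perturbed) SDF tensor from stereotype rates.

    Evaluates each unit's stereotype rate at the right edges of ``n_bins``
    normalized bins of each duration, i.e. at ``t = (i+1)/n_bins * duration``.
    Returns an array of shape (units, stimuli, n_bins) in Hz. If any unit has
    ``noise_sd > 0`` a ``seed`` must be supplied; independent Gaussian rate
    noise is then added per bin and rectified at 0.
    """
    durations = np.asarray(durations, dtype=float)
    rng = _as_rng(seed) if seed is not None else None
    frac = (np.arange(n_bins) + 1) / n_bins
    out = np.empty((len(population), len(durations), n_bins))
    for u, params in enumerate(population):
        for j, d in enumerate(durations):
            trace = stereotype_rate(params, d, frac * d)
            if params.noise_sd > 0:
                if rng is None:
                    raise ValueError("seed required when rate noise is enabled")
                trace = np.maximum(trace + rng.normal(0, params.noise_sd, n_bins), 0.0)
            out[u, j] = trace
    return out


# ---------------------------------------------------------------------------
# session I/O
# ---------------------------------------------------------------------------


def write_session_hdf5(path, trials: list[TrialRecord], spikes: SpikeData) -> None:
    """Write a session to HDF5: one group per unit, one spike-time dataset
    per trial, phase markers as attributes, and the trial table as a group."""
    import h5py

    with h5py.File(path, "w") as f:
        units = f.create_group("units")
        for u, unit_trains in enumerate(spikes.trains):
            g = units.create_group(f"unit_{u:04d}")
            for i, train in enumerate(unit_trains):
                d = g.create_dataset(f"trial_{i:04d}", data=np.asarray(train))
                d.attrs["phases"] = spikes.phases[i]
        tg = f.create_group("trials")
        tg.create_dataset("stimulus_s", data=[t.stimulus for t in trials])
        tg.create_dataset("reproduction_s", data=[t.reproduction for t in trials])
        tg.create_dataset("tolerance", data=[t.tolerance for t in trials])
        tg.create_dataset("reward", data=[int(t.reward) for t in trials])
        tg.create_dataset("gain", data=[t.gain for t in trials])
        tg.create_dataset("phases", data=spikes.phases)
        sg = f.create_group("speed")
        sg.attrs["dt"] = trials[0].speed_dt if trials else 0.05
        for i, t in enumerate(trials):
            if t.speed is not None:
                sg.create_dataset(f"trial_{i:04d}", data=t.speed)


def read_session_hdf5(path) -> tuple[list[TrialRecord], SpikeData]:
    import h5py

    with h5py.File(path, "r") as f:
        tg = f["trials"]
        phases = tg["phases"][...]
        stim = tg["stimulus_s"][...]
        repro = tg["reproduction_s"][...]
        tol = tg["tolerance"][...]
        reward = tg["reward"][...]
        gain = tg["gain"][...]
        dt = float(f["speed"].attrs.get("dt", 0.05)) if "speed" in f else 0.05
        trials = []
        for i in range(len(stim)):
            speed = None
            key = f"trial_{i:04d}"
            if "speed" in f and key in f["speed"]:
                speed = f["speed"][key][...]
            trials.append(
                TrialRecord(
                    stimulus=float(stim[i]),
                    reproduction=float(repro[i]),
                    tolerance=float(tol[i]),
                    reward=bool(reward[i]),
                    gain=float(gain[i]),
                    speed=speed,
                    speed_dt=dt,
                )
            )
        trains = []
        unit_keys = sorted(f["units"].keys())
        for uk in unit_keys:
            g = f["units"][uk]
            trains.append([g[f"trial_{i:04d}"][...] for i in range(len(stim))])
    spikes = SpikeData(trains=trains, phases=phases, stimuli=stim, reproductions=repro)
    return trials, spikes


def write_session_csv(outdir, trials: list[TrialRecord], spikes: SpikeData) -> None:
    """Write ``trials.csv`` and long-format ``spikes.csv`` into ``outdir``."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tdf = pd.DataFrame(
        {
            "trial_id": np.arange(len(trials)),
            "stimulus_s": [t.stimulus for t in trials],
            "reproduction_s": [t.reproduction for t in trials],
            "k": [t.tolerance for t in trials],
            "reward": [int(t.reward) for t in trials],
            "gain": [t.gain for t in trials],
            "t0": spikes.phases[:, 0],
            "t1": spikes.phases[:, 1],
            "t2": spikes.phases[:, 2],
            "t3": spikes.phases[:, 3],
        }
    )
    tdf.to_csv(outdir / "trials.csv", index=False)
    rows = []
    for u, unit_trains in enumerate(spikes.trains):
        for i, train in enumerate(unit_trains):
            for t in train:
                rows.append((i, u, t))
    sdf = pd.DataFrame(rows, columns=["trial_id", "unit_id", "spike_time_s"])
    sdf.to_csv(outdir / "spikes.csv", index=False)


def read_session_csv(outdir) -> tuple[list[TrialRecord], SpikeData]:
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    tdf = pd.read_csv(outdir / "trials.csv")
    sdf = pd.read_csv(outdir / "spikes.csv")
    phases = tdf[["t0", "t1", "t2", "t3"]].to_numpy()
    trials = [
        TrialRecord(
            stimulus=row.stimulus_s,
            reproduction=row.reproduction_s,
            tolerance=row.k,
            reward=bool(row.reward),
            gain=row.gain,
        )
        for row in tdf.itertuples()
    ]
    n_trials = len(tdf)
    n_units = int(sdf["unit_id"].max()) + 1 if len(sdf) else 0
    trains = [
        [np.empty(0) for _ in range(n_trials)] for _ in range(n_units)
    ]
    for (u, i), group in sdf.groupby(["unit_id", "trial_id"]):
        trains[int(u)][int(i)] = np.sort(group["spike_time_s"].to_numpy())
    spikes = SpikeData(
        trains=trains,
        phases=phases,
        stimuli=tdf["stimulus_s"].to_numpy(),
        reproductions=tdf["reproduction_s"].to_numpy(),
    )
    return trials, spikes
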