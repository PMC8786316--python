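import numpy as np
import pytest

from timepop import sdf as sdf_mod
from timepop.synthetic import (
    DEFAULT_GRID,
    SessionConfig,
    StereotypeParams,
    generate_session,
    rate_tensor,
)

DURATIONS = np.asarray(DEFAULT_GRID.durations)


def stereotype_pool(kind, n, rng, **overrides):
    """Heterogeneous pool of one stereotype kind."""
    pool = []
    for _ in range(n):
        kw = dict(
            kind=kind,
            baseline=rng.uniform(0.5, 3.0),
            amplitude=rng.uniform(5.0, 15.0),
            slope=rng.uniform(0.5, 3.0),
            peak_time=rng.uniform(0.5, 2.9),
            phase=rng.uniform(0.1, 0.9),
            peak_width=rng.uniform(0.3, 0.8),
        )
        kw.update(overrides)
        pool.append(StereotypeParams(**kw))
    return pool


def ztensor(population, durations=DURATIONS, n_bins=40, seed=None, phase="measurement"):
    """Normalized, z-scored SDF tensor built from stereotype rate profiles."""
    values = rate_tensor(population, durations, n_bins, seed=seed)
    raw = sdf_mod.from_rates(values, durations, phase=phase)
    return sdf_mod.normalize_and_zscore(raw, n_bins)


def noise_tensor(n_units, rng, durations=DURATIONS, n_bins=40, phase="measurement"):
    """Pure white-noise z-scored tensor (global null)."""
    values = rng.standard_normal((n_units, len(durations), n_bins))
    raw = sdf_mod.from_rates(values, durations, phase=phase)
    return sdf_mod.normalize_and_zscore(raw, n_bins)


@pytest.fixture(scope="session")
def small_session():
    """One small but complete synthetic session shared across tests."""
    cfg = SessionConfig(n_trials=35, n_units=6, rate_noise_sd=0.0, seed=11)
    trials, spikes = generate_session(cfg)
    return cfg, trials, spikes
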