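"""Linear (Wiener-filter) decoding of elapsed time from population SDFs.

The design matrix R stacks every unit's time-normalized, z-scored SDFs for
all stimuli (rows = stimuli x bins, columns = units); the target t holds the
real elapsed time at each normalized bin, ``t = (i+1)/n_bins * duration(s)``,
so final targets differ across stimuli. Weights solve ``[R, 1] [beta; c] = t``
by least squares — the decoder is a weighted sum of rates plus an intercept,
the standard Wiener-filter formulation. To avoid overfitting, zero-mean
Gaussian noise (default SD 0.5, in z-units) is added to R at fit time only;
with no noise the solution is the minimum-norm pseudoinverse solution.

The regression effect is quantified by the OLS slope of the final decoded
values on the true durations across stimuli: linear-increasing populations
(fixed slope, stimulus-dependent end level) give slope ~ 1 (veridical
timing); ramp-to-threshold populations (stimulus-invariant normalized
profile) can only decode the mean duration, giving slope ~ 0 (maximal
regression); mixtures interpolate, with more slope-changing cells giving
stronger regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sdf import SDFTensor

__all__ = [
    "DecoderWeights",
    "DecodeResult",
    "BootstrapDecode",
    "build_design",
    "fit_time_decoder",
    "decode_and_slope",
    "bootstrap_decode",
    "mixture_sweep",
]


@dataclass
class DecoderWeights:
    beta: np.ndarray  # one weight per unit
    intercept: float


def build_design(sdf: SDFTensor, durations=None) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and elapsed-time target.

    Rows are stacked stimulus-by-stimulus; for stimulus ``s`` at normalized
    bin ``i`` the target is ``(i+1)/n_bins * duration(s)`` seconds.
    """
    durations = np.asarray(sdf.durations if durations is None else durations, dtype=float)
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    values = sdf.values  # (units, stimuli, bins)
    n_units, n_stimuli, n_bins = values.shape
    if len(durations) != n_stimuli:
        raise ValueError("one duration per stimulus required")
    R = values.transpose(1, 2, 0).reshape(n_stimuli * n_bins, n_units)
    frac = (np.arange(n_bins) + 1) / n_bins
    t = (durations[:, None] * frac[None, :]).ravel()
    return R, t


def fit_time_decoder(
    R: np.ndarray, t: np.ndarray, noise_sd: float = 0.5, seed=0
) -> DecoderWeights:
    """Least-squares weights of the time decoder.

    Gaussian noise with SD ``noise_sd`` is added to R (not to the intercept
    column and not at decode time); with ``noise_sd=0`` the fit equals the
    minimum-norm pseudoinverse solution.
    """
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    if R.ndim != 2 or R.shape[0] < 1:
        raise ValueError("R must be a 2-D matrix with at least one row")
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        R = R + rng.normal(0.0, noise_sd, R.shape)
    A = np.column_stack([R, np.ones(R.shape[0])])
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    return DecoderWeights(beta=coef[:-1], intercept=float(coef[-1]))


@dataclass
class DecodeResult:
    decoded: np.ndarray  # (stimuli, bins) seconds
    finals: np.ndarray  # (stimuli,) last-bin decoded values
    slope: float  # OLS slope of finals on true durations
    intercept: float
    durations: np.ndarray


def decode_and_slope(
    weights: DecoderWeights, sdf: SDFTensor, durations=None
) -> DecodeResult:
    """Decode per-stimulus time series and regress final values on durations."""
    durations = np.asarray(sdf.durations if durations is None else durations, dtype=float)
    values = sdf.values
    decoded = np.einsum("usb,u->sb", values, weights.beta) + weights.intercept
    finals = decoded[:, -1]
    if len(durations) >= 2 and np.std(durations) > 0 and np.std(finals) > 0:
        fit = stats.linregress(durations, finals)
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif len(durations) >= 2 and np.std(durations) > 0:
        slope, intercept = 0.0, float(finals.mean())
    else:
        slope, intercept = float("nan"), float("nan")
    return DecodeResult(
        decoded=decoded, finals=finals, slope=slope, intercept=intercept, durations=durations
    )


@dataclass
class BootstrapDecode:
    decoded_mean: np.ndarray  # (stimuli, bins)
    decoded_sd: np.ndarray
    slopes: np.ndarray  # (runs,)
    median_slope: float
    iqr: tuple[float, float]
    durations: np.ndarray


def bootstrap_decode(
    sdf: SDFTensor,
    durations=None,
    subset_size: int = 20,
    runs: int = 1000,
    noise_sd: float = 0.5,
    seed=0,
) -> BootstrapDecode:
    """Fit and decode on random unit subsets; aggregate across runs.

    Per run, ``subset_size`` units are sampled without replacement, the
    decoder is fit on that subset's design (with fresh fit noise) and the
    decoded series recorded; the summary reports mean +/- SD of the decoded
    series and median plus interquartile range of the final-value slopes.
    """
    durations = np.asarray(sdf.durations if durations is None else durations, dtype=float)
    values = sdf.values
    n_units = values.shape[0]
    if subset_size > n_units:
        raise ValueError("subset_size exceeds the number of units")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    decoded = np.empty((runs, values.shape[1], values.shape[2]))
    slopes = np.empty(runs)
    for run in range(runs):
        subset = rng.choice(n_units, subset_size, replace=False)
        sub = sdf.with_values(values[subset])
        R, t = build_design(sub, durations)
        w = fit_time_decoder(R, t, noise_sd=noise_sd, seed=rng)
        res = decode_and_slope(w, sub, durations)
        decoded[run] = res.decoded
        slopes[run] = res.slope
    q25, q75 = np.percentile(slopes, [25, 75])
    return BootstrapDecode(
        decoded_mean=decoded.mean(axis=0),
        decoded_sd=decoded.std(axis=0),
        slopes=slopes,
        median_slope=float(np.median(slopes)),
        iqr=(float(q25), float(q75)),
        durations=durations,
    )


def mixture_sweep(
    pool_changing: SDFTensor,
    pool_linear: SDFTensor,
    fractions=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    subset_size: int = 20,
    runs: int = 1000,
    noise_sd: float = 0.5,
    seed=0,
    durations=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median final-value slope as a function of the slope-changing fraction.

    ``pool_changing`` holds slope-changing (ramp-to-threshold-like) units and
    ``pool_linear`` linear-increasing units on identical stimuli/bins. For
    each fraction ``p``, every bootstrap run samples ``round(p*subset_size)``
    units from the changing pool and the rest from the linear pool, fits and
    decodes, and the median slope across runs is recorded.

    Returns ``(fractions, median_slopes, all_slopes)`` with ``all_slopes``
    shaped (len(fractions), runs).
    """
    vc, vl = pool_changing.values, pool_linear.values
    if vc.shape[1:] != vl.shape[1:]:
        raise ValueError("pools must share stimuli and bin count")
    durations = np.asarray(
        pool_changing.durations if durations is None else durations, dtype=float
    )
    fractions = np.asarray(fractions, dtype=float)
    rng = np.random.default_rng(seed)
    medians = np.empty(len(fractions))
    all_slopes = np.empty((len(fractions), runs))
    for i, p in enumerate(fractions):
        n_c = int(round(p * subset_size))
        n_l = subset_size - n_c
        if n_c > vc.shape[0] or n_l > vl.shape[0]:
            raise ValueError("pool too small for requested subset size")
        for run in range(runs):
            parts = []
            if n_c:
                parts.append(vc[rng.choice(vc.shape[0], n_c, replace=False)])
            if n_l:
                parts.append(vl[rng.choice(vl.shape[0], n_l, replace=False)])
            mixed = np.concatenate(parts, axis=0)
            sub = pool_changing.with_values(mixed)
            R, t = build_design(sub, durations)
            w = fit_time_decoder(R, t, noise_sd=noise_sd, seed=rng)
            all_slopes[i, run] = decode_and_slope(w, sub, durations).slope
        medians[i] = np.median(all_slopes[i])
    return fractions, medians, all_slopes
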