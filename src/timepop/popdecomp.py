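"""Demixed and conventional decomposition of population activity.

The (units x stimuli x bins) z-scored tensor is split additively into a
stimulus-independent time marginal (the mean over stimuli) and a stimulus
marginal (the remainder, which sums to zero over stimuli at every unit and
bin). An SVD of each marginal yields

* time components — bins-long traces identical across stimuli by
  construction ("perfect demixing"),
* stimulus components — one spatial component whose per-stimulus trace
  carries an amplitude per stimulus (ordered by duration for
  duration-tuned populations),

with per-unit scores and the percentage of total tensor variance explained
by each component. Because the two marginals are orthogonal in the
sum-of-squares sense, explained variances of time components, stimulus
components and the residual add to 100%.

Conventional PCA applies the same SVD to the full per-stimulus tensor, so
its per-stimulus trajectories mix time-course and stimulus information;
trajectory length and mean speed per stimulus are measured in the space of
the leading components. Interaction (stimulus x time) variance is left in
the residual; no cross-marginal regularization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sdf import SDFTensor

__all__ = [
    "DecompResult",
    "BootstrapDecomp",
    "marginalize",
    "demixed_pca",
    "conventional_pca",
    "trajectory_metrics",
    "bootstrap_decomp",
]


def marginalize(sdf: SDFTensor) -> tuple[np.ndarray, np.ndarray]:
    """Split the tensor into time and stimulus marginals.

    Returns ``(time_marginal, stimulus_marginal)`` with shapes
    (units, bins) and (units, stimuli, bins); broadcasting the time marginal
    over stimuli and adding the stimulus marginal reconstructs the tensor
    exactly.
    """
    values = sdf.values
    time_marginal = values.mean(axis=1)
    stimulus_marginal = values - time_marginal[:, None, :]
    return time_marginal, stimulus_marginal


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-magnitude element is positive."""
    for j in range(components.shape[0]):
        flat = components[j].ravel()
        if len(flat) and flat[np.argmax(np.abs(flat))] < 0:
            components[j] = -components[j]
            scores[:, j] = -scores[:, j]


def _svd_truncate(M: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leading-k SVD factors, zero-padded when rank (or size) falls short."""
    n_units, n_feat = M.shape
    if np.sum(M * M) < 1e-24:
        return (
            np.zeros((n_units, k)),
            np.zeros(k),
            np.zeros((k, n_feat)),
        )
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    r = min(k, len(S))
    scores = np.zeros((n_units, k))
    svals = np.zeros(k)
    comps = np.zeros((k, n_feat))
    scores[:, :r] = U[:, :r] * S[:r]
    svals[:r] = S[:r]
    comps[:r] = Vt[:r]
    return scores, svals, comps


@dataclass
class DecompResult:
    """Result of a population decomposition.

    ``time_components`` are unit-norm bins-long traces; ``stim_components``
    hold each stimulus component as a (stimuli, bins) trace whose
    per-stimulus mean over bins is reported in ``stim_amplitudes``.
    ``ev_*`` give the percentage of total tensor variance explained by each
    component.
    """

    kind: str
    time_components: np.ndarray
    time_scores: np.ndarray
    ev_time: np.ndarray
    stim_components: np.ndarray
    stim_scores: np.ndarray
    stim_amplitudes: np.ndarray
    ev_stim: np.ndarray
    stimuli: np.ndarray
    durations: np.ndarray
    total_ss: float

    @property
    def n_time(self) -> int:
        return self.time_components.shape[0]

    @property
    def n_stim_components(self) -> int:
        return self.stim_components.shape[0]


def demixed_pca(sdf: SDFTensor, n_time_pcs: int = 3, n_stim_pcs: int = 1) -> DecompResult:
    """Marginalization-based demixed PCA.

    SVD is applied separately to the time marginal (units x bins) and to the
    flattened stimulus marginal (units x stimuli*bins). Component signs are
    fixed so the largest-magnitude element is positive; decompositions are
    therefore deterministic.
    """
    values = sdf.values
    if sdf.n_units < max(n_time_pcs, n_stim_pcs):
        raise ValueError("need at least as many units as requested components")
    n_stimuli = sdf.n_stimuli
    total_ss = float(np.sum(values * values))
    total_ss_safe = total_ss if total_ss > 0 else 1.0

    time_marginal, stim_marginal = marginalize(sdf)
    t_scores, t_svals, t_comps = _svd_truncate(time_marginal, n_time_pcs)
    _fix_signs(t_comps, t_scores)
    # the time marginal appears once per stimulus in the full tensor
    ev_time = 100.0 * n_stimuli * t_svals**2 / total_ss_safe

    M = stim_marginal.reshape(sdf.n_units, -1)
    s_scores, s_svals, s_comps_flat = _svd_truncate(M, n_stim_pcs)
    s_comps = s_comps_flat.reshape(n_stim_pcs, n_stimuli, values.shape[2])
    _fix_signs(s_comps, s_scores)
    ev_stim = 100.0 * s_svals**2 / total_ss_safe
    amplitudes = s_comps.mean(axis=2)

    return DecompResult(
        kind="demixed",
        time_components=t_comps,
        time_scores=t_scores,
        ev_time=ev_time,
        stim_components=s_comps,
        stim_scores=s_scores,
        stim_amplitudes=amplitudes,
        ev_stim=ev_stim,
        stimuli=sdf.stimuli.copy(),
        durations=sdf.durations.copy(),
        total_ss=total_ss,
    )


def conventional_pca(sdf: SDFTensor, n_pcs: int = 3) -> DecompResult:
    """Standard SVD of the full (units x stimuli*bins) tensor.

    Components are returned as per-stimulus trajectories (stimuli, bins) in
    ``stim_components``; with a single stimulus they coincide with the
    demixed time components. ``time_components`` hold the across-stimulus
    mean trace of each component for convenience.
    """
    values = sdf.values
    if sdf.n_units < n_pcs:
        raise ValueError("need at least as many units as requested components")
    total_ss = float(np.sum(values * values))
    total_ss_safe = total_ss if total_ss > 0 else 1.0
    M = values.reshape(sdf.n_units, -1)
    scores, svals, comps_flat = _svd_truncate(M, n_pcs)
    comps = comps_flat.reshape(n_pcs, sdf.n_stimuli, values.shape[2])
    _fix_signs(comps, scores)
    ev = 100.0 * svals**2 / total_ss_safe
    return DecompResult(
        kind="conventional",
        time_components=comps.mean(axis=1),
        time_scores=scores,
        ev_time=ev,
        stim_components=comps,
        stim_scores=scores,
        stim_amplitudes=comps.mean(axis=2),
        ev_stim=ev,
        stimuli=sdf.stimuli.copy(),
        durations=sdf.durations.copy(),
        total_ss=total_ss,
    )


def trajectory_metrics(
    result: DecompResult, sdf: SDFTensor, top_k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulus trajectory length and mean speed in top-k PC space.

    The population state at stimulus ``s`` and bin ``i`` is the projection of
    the tensor onto the unit-norm score directions of the leading ``top_k``
    components; length sums Euclidean steps between consecutive bins, and
    mean speed divides by the stimulus' real duration.
    """
    values = sdf.values
    scores = result.time_scores[:, :top_k]
    norms = np.linalg.norm(scores, axis=0)
    norms[norms < 1e-12] = 1.0
    directions = scores / norms  # (units, top_k)
    traj = np.einsum("usb,uk->skb", values, directions)  # (stimuli, top_k, bins)
    steps = np.diff(traj, axis=2)
    lengths = np.linalg.norm(steps, axis=1).sum(axis=1)
    speeds = lengths / result.durations
    return lengths, speeds


@dataclass
class BootstrapDecomp:
    """Aggregated bootstrap decompositions (sign-aligned to the full fit)."""

    full: DecompResult
    time_components: np.ndarray  # (runs, k, bins)
    stim_amplitudes: np.ndarray  # (runs, m, stimuli)
    ev_time: np.ndarray  # (runs, k)
    ev_stim: np.ndarray  # (runs, m)
    score_corr: np.ndarray  # (runs, k): corr(time PC_j scores, stim PC1 scores)
    score_corr_p: np.ndarray

    def band(self, component: int = 0, n_sd: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        mean = self.time_components[:, component].mean(axis=0)
        sd = self.time_components[:, component].std(axis=0)
        return mean - n_sd * sd, mean + n_sd * sd


def _score_correlation(time_scores: np.ndarray, stim_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy import stats as _st

    k = time_scores.shape[1]
    r = np.full(k, np.nan)
    p = np.full(k, np.nan)
    y = stim_scores[:, 0]
    for j in range(k):
        x = time_scores[:, j]
        if x.std() > 1e-12 and y.std() > 1e-12 and len(x) > 2:
            res = _st.pearsonr(x, y)
            r[j], p[j] = res.statistic, res.pvalue
    return r, p


def bootstrap_decomp(
    sdf: SDFTensor,
    frac: float = 0.1,
    runs: int = 1000,
    strata=None,
    seed=0,
    n_time_pcs: int = 3,
    n_stim_pcs: int = 1,
) -> BootstrapDecomp:
    """Stratified subsampled demixed PCAs.

    Each run draws ``frac`` of the units without replacement within each
    stratum (e.g., animal of origin), refits the decomposition, aligns
    component signs to the full-data fit, and records components, explained
    variances and the correlation of each time PC's scores with the stimulus
    PC 1 scores.
    """
    full = demixed_pca(sdf, n_time_pcs, n_stim_pcs)
    n_units = sdf.n_units
    strata = np.zeros(n_units, dtype=int) if strata is None else np.asarray(strata)
    if len(strata) != n_units:
        raise ValueError("strata must provide one label per unit")
    groups = []
    for label in np.unique(strata):
        idx = np.flatnonzero(strata == label)
        take = int(round(frac * len(idx)))
        if take < 1:
            raise ValueError(f"stratum {label!r} too small for frac={frac}")
        groups.append((idx, take))

    rng = np.random.default_rng(seed)
    n_bins = sdf.n_bins
    tc = np.empty((runs, n_time_pcs, n_bins))
    amp = np.empty((runs, n_stim_pcs, sdf.n_stimuli))
    evt = np.empty((runs, n_time_pcs))
    evs = np.empty((runs, n_stim_pcs))
    sc = np.empty((runs, n_time_pcs))
    scp = np.empty((runs, n_time_pcs))
    values = sdf.values
    for run in range(runs):
        subset = np.concatenate(
            [rng.choice(idx, take, replace=False) for idx, take in groups]
        )
        sub = sdf.with_values(values[subset][:, :, :])
        res = demixed_pca(sub, n_time_pcs, n_stim_pcs)
        # align signs with the full-data components before aggregating
        for j in range(n_time_pcs):
            if np.dot(res.time_components[j], full.time_components[j]) < 0:
                res.time_components[j] *= -1
                res.time_scores[:, j] *= -1
        for m in range(n_stim_pcs):
            if np.sum(res.stim_components[m] * full.stim_components[m]) < 0:
                res.stim_components[m] *= -1
                res.stim_scores[:, m] *= -1
                res.stim_amplitudes[m] *= -1
        tc[run] = res.time_components
        amp[run] = res.stim_amplitudes
        evt[run] = res.ev_time
        evs[run] = res.ev_stim
        sc[run], scp[run] = _score_correlation(res.time_scores, res.stim_scores)
    return BootstrapDecomp(
        full=full,
        time_components=tc,
        stim_amplitudes=amp,
        ev_time=evt,
        ev_stim=evs,
        score_corr=sc,
        score_corr_p=scp,
    )
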