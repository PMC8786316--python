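"""Response-type categorization from decomposition scores.

Each unit's traces are reconstructed as a linear combination of a fixed set
of candidate components (measurement: time PC 1 and stimulus PC 1;
reproduction: time PCs 1-3 and stimulus PC 1) weighted by the unit's scores.
If the reconstruction explains less variance than a phase-specific threshold
(defaults 6% for measurement, 28% for reproduction) the unit is 'unrelated
activity'. Otherwise the strongest component (largest absolute score) always
contributes, and any other component contributes iff the angle
``arctan(|score_j| / |score_strongest|)`` exceeds 22.5 degrees — i.e. iff its
absolute score exceeds ``tan(22.5 deg) ~ 0.414`` times the strongest. With K
candidate components this yields a 2^K category lattice (the empty set being
'unrelated activity'); the rule is invariant to global sign flips of the
components.

Chance-level category counts come from surrogate populations in which SDF
traces are shuffled across stimuli and cells before re-running the
decomposition and categorization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .popdecomp import DecompResult, demixed_pca
from .sdf import SDFTensor

__all__ = [
    "CategoryAssignment",
    "candidate_components",
    "reconstruct_unit",
    "assign_category",
    "category_space_size",
    "categorize_population",
    "maximum_likelihood_categories",
    "chance_category_counts",
    "transition_table",
    "DEFAULT_EV_THRESHOLDS",
]

#: Reconstruction-EV thresholds below which a unit is 'unrelated activity'.
DEFAULT_EV_THRESHOLDS = {"measurement": 6.0, "reproduction": 28.0}

ANGLE_THRESHOLD_DEG = 22.5


@dataclass
class CategoryAssignment:
    unit: int
    phase: str
    category: frozenset
    ev: float

    @property
    def unrelated(self) -> bool:
        return len(self.category) == 0


def candidate_components(
    result: DecompResult, phase: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Candidate component set for one phase.

    Returns ``(names, components, scores)`` with components shaped
    (K, stimuli, bins) — time components broadcast across stimuli — and
    scores shaped (units, K). Measurement uses time PC 1 + stimulus PC 1;
    reproduction uses time PCs 1-3 + stimulus PC 1.

    All components are normalized to unit Frobenius norm in the common
    (stimuli, bins) space and the scores rescaled to match: a replicated
    time component carries norm sqrt(n_stimuli), so without this rescaling
    time and stimulus scores would not be comparable in the angle rule.
    """
    n_time = 1 if phase == "measurement" else 3
    if phase not in ("measurement", "reproduction"):
        raise ValueError("phase must be 'measurement' or 'reproduction'")
    if result.n_time < n_time:
        raise ValueError(f"decomposition provides too few time components for {phase}")
    names = [f"PC{j + 1}" for j in range(n_time)] + ["sPC1"]
    n_stimuli, n_bins = result.stim_components.shape[1:]
    comps = np.empty((n_time + 1, n_stimuli, n_bins))
    scale = np.sqrt(n_stimuli)
    for j in range(n_time):
        comps[j] = np.broadcast_to(result.time_components[j], (n_stimuli, n_bins)) / scale
    comps[n_time] = result.stim_components[0]
    scores = np.column_stack(
        [result.time_scores[:, :n_time] * scale, result.stim_scores[:, :1]]
    )
    return names, comps, scores


def reconstruct_unit(
    scores: np.ndarray,
    components: np.ndarray,
    traces: np.ndarray,
    subset=None,
) -> tuple[np.ndarray, float]:
    """Linear reconstruction of one unit's traces and its explained variance.

    ``scores`` has one entry per candidate component, ``components`` is
    (K, stimuli, bins) and ``traces`` is the unit's (stimuli, bins) data.
    ``subset`` restricts the combination to some component indices (empty
    subset reconstructs zero). EV is ``1 - SS_res / SS_tot`` in percent,
    clipped to [0, 100].
    """
    K = components.shape[0]
    subset = range(K) if subset is None else list(subset)
    recon = np.zeros_like(traces, dtype=float)
    for j in subset:
        recon += scores[j] * components[j]
    ss_tot = float(np.sum(traces * traces))
    if ss_tot <= 0:
        return recon, 0.0
    ss_res = float(np.sum((traces - recon) ** 2))
    ev = 100.0 * (1.0 - ss_res / ss_tot)
    return recon, float(np.clip(ev, 0.0, 100.0))


def assign_category(
    unit: int,
    scores: np.ndarray,
    components: np.ndarray,
    traces: np.ndarray,
    names: list[str],
    phase: str,
    ev_threshold: float,
    angle_threshold_deg: float = ANGLE_THRESHOLD_DEG,
) -> CategoryAssignment:
    """Assign one unit its contributing-component set."""
    _, ev = reconstruct_unit(scores, components, traces)
    abs_scores = np.abs(np.asarray(scores, dtype=float))
    if ev < ev_threshold or not np.any(abs_scores > 0):
        return CategoryAssignment(unit=unit, phase=phase, category=frozenset(), ev=ev)
    strongest = int(np.argmax(abs_scores))
    members = {names[strongest]}
    for j in range(len(names)):
        if j == strongest:
            continue
        angle = np.degrees(np.arctan2(abs_scores[j], abs_scores[strongest]))
        if angle > angle_threshold_deg:
            members.add(names[j])
    return CategoryAssignment(unit=unit, phase=phase, category=frozenset(members), ev=ev)


def category_space_size(n_components: int) -> int:
    """Number of possible response types with n candidate components
    (the power set, including the empty 'unrelated activity' set)."""
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    return 2**n_components


def categorize_population(
    sdf: SDFTensor,
    result: DecompResult,
    phase: str,
    ev_threshold: float | None = None,
) -> list[CategoryAssignment]:
    """Categorize every unit of a tensor from one decomposition."""
    if ev_threshold is None:
        ev_threshold = DEFAULT_EV_THRESHOLDS[phase]
    names, comps, scores = candidate_components(result, phase)
    values = sdf.values
    return [
        assign_category(u, scores[u], comps, values[u], names, phase, ev_threshold)
        for u in range(sdf.n_units)
    ]


def _project_scores(values: np.ndarray, comps: np.ndarray) -> np.ndarray:
    """Scores of all units w.r.t. (orthonormal) components by projection."""
    flat_comps = comps.reshape(comps.shape[0], -1)
    flat_vals = values.reshape(values.shape[0], -1)
    return flat_vals @ flat_comps.T


def maximum_likelihood_categories(
    sdf: SDFTensor,
    phase: str,
    frac: float = 0.1,
    runs: int = 100,
    seed=0,
    ev_threshold: float | None = None,
    strata=None,
) -> list[CategoryAssignment]:
    """Bootstrap-stabilized labels: every unit is categorized against each
    subsampled decomposition (scores by projection onto the run's
    components) and receives its modal category; ties break toward the
    smaller component set."""
    from .popdecomp import bootstrap_decomp  # local import to avoid cycle at module load

    if ev_threshold is None:
        ev_threshold = DEFAULT_EV_THRESHOLDS[phase]
    n_time = 1 if phase == "measurement" else 3
    values = sdf.values
    votes: list[Counter] = [Counter() for _ in range(sdf.n_units)]
    evs = np.zeros(sdf.n_units)

    rng = np.random.default_rng(seed)
    n_units = sdf.n_units
    strata_arr = np.zeros(n_units, dtype=int) if strata is None else np.asarray(strata)
    for _ in range(runs):
        subset = []
        for label in np.unique(strata_arr):
            idx = np.flatnonzero(strata_arr == label)
            take = max(1, int(round(frac * len(idx))))
            subset.append(rng.choice(idx, take, replace=False))
        subset = np.concatenate(subset)
        sub = sdf.with_values(values[subset])
        res = demixed_pca(sub, n_time_pcs=max(n_time, 1), n_stim_pcs=1)
        names, comps, _ = candidate_components(res, phase)
        proj = _project_scores(values, comps)
        for u in range(n_units):
            a = assign_category(
                u, proj[u], comps, values[u], names, phase, ev_threshold
            )
            votes[u][a.category] += 1
            evs[u] += a.ev
    out = []
    for u in range(n_units):
        best = max(votes[u].items(), key=lambda kv: (kv[1], -len(kv[0])))
        out.append(
            CategoryAssignment(unit=u, phase=phase, category=best[0], ev=evs[u] / runs)
        )
    return out


def chance_category_counts(
    sdf: SDFTensor,
    phase: str,
    runs: int = 1000,
    seed=0,
    ev_threshold: float | None = None,
    n_time_pcs: int = 3,
) -> dict:
    """Observed vs chance category counts.

    Surrogates shuffle SDF traces across stimuli and cells, re-run the
    demixed PCA and categorization, and count units per category; the
    empirical two-sided p-value compares the observed count with the
    surrogate distribution, with a '<' / '>' direction flag.
    """
    result = demixed_pca(sdf, n_time_pcs=n_time_pcs, n_stim_pcs=1)
    observed = Counter(a.category for a in categorize_population(sdf, result, phase, ev_threshold))

    rng = np.random.default_rng(seed)
    values = sdf.values
    n_units, n_stimuli, n_bins = values.shape
    surrogate_counts: dict[frozenset, np.ndarray] = {}
    all_categories = set(observed)
    per_run: list[Counter] = []
    for _ in range(runs):
        flat = values.reshape(n_units * n_stimuli, n_bins)
        shuffled = flat[rng.permutation(flat.shape[0])].reshape(values.shape)
        surr = sdf.with_values(shuffled)
        res = demixed_pca(surr, n_time_pcs=n_time_pcs, n_stim_pcs=1)
        counts = Counter(a.category for a in categorize_population(surr, res, phase, ev_threshold))
        per_run.append(counts)
        all_categories.update(counts)
    report = {}
    for cat in all_categories:
        surr = np.array([c.get(cat, 0) for c in per_run])
        obs = observed.get(cat, 0)
        ge = np.mean(surr >= obs)
        le = np.mean(surr <= obs)
        p = min(1.0, 2.0 * min(ge, le))
        direction = ">" if obs > np.median(surr) else ("<" if obs < np.median(surr) else "=")
        report[cat] = {
            "observed": int(obs),
            "surrogate_mean": float(surr.mean()),
            "p": float(p),
            "direction": direction,
        }
    return report


def transition_table(
    assign_meas: list[CategoryAssignment],
    assign_repro: list[CategoryAssignment],
) -> dict:
    """Measurement-to-reproduction category transitions and activity shares.

    Returns contingency counts over (measurement category, reproduction
    category) plus the share of units active in both phases, one phase only,
    or neither (a unit is 'active' in a phase iff not 'unrelated').
    """
    if len(assign_meas) != len(assign_repro):
        raise ValueError("assignments must cover the same unit set")
    units_m = [a.unit for a in assign_meas]
    units_r = [a.unit for a in assign_repro]
    if units_m != units_r:
        raise ValueError("assignments must cover the same unit set in the same order")
    counts: Counter = Counter()
    shares = Counter()
    for am, ar in zip(assign_meas, assign_repro):
        counts[(am.category, ar.category)] += 1
        if not am.unrelated and not ar.unrelated:
            shares["both"] += 1
        elif not am.unrelated:
            shares["measurement_only"] += 1
        elif not ar.unrelated:
            shares["reproduction_only"] += 1
        else:
            shares["neither"] += 1
    n = len(assign_meas)
    return {
        "counts": dict(counts),
        "activity_shares": {k: shares.get(k, 0) / n for k in
                            ("both", "measurement_only", "reproduction_only", "neither")},
        "n_units": n,
    }
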