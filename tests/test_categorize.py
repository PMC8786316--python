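"""Response-type categorization: reconstruction EV, angle rule, surrogates."""

import numpy as np
import pytest

from conftest import DURATIONS
from timepop import sdf as S
from timepop.categorize import (
    assign_category,
    candidate_components,
    categorize_population,
    category_space_size,
    chance_category_counts,
    maximum_likelihood_categories,
    reconstruct_unit,
    transition_table,
    CategoryAssignment,
)
from timepop.popdecomp import demixed_pca


def _orthonormal_components(n_bins=40):
    ramp = np.linspace(-1, 1, n_bins)
    ramp /= np.linalg.norm(ramp)
    c = (DURATIONS - DURATIONS.mean())
    c /= np.linalg.norm(c)
    comps = np.stack(
        [
            np.broadcast_to(ramp, (len(DURATIONS), n_bins)) / np.sqrt(len(DURATIONS)),
            np.repeat(c[:, None], n_bins, axis=1) / np.sqrt(n_bins),
        ]
    )
    return comps  # each has unit Frobenius norm, mutually orthogonal


def _planted_population(rng, n_pc1=30, n_spc1=30, n_both=20, n_none=20, noise=0.02):
    """Tensor with units loading on a ramp factor, a stimulus factor, both,
    or neither; returns (tensor, expected category names per unit)."""
    comps = _orthonormal_components()
    units, labels = [], []
    for _ in range(n_pc1):
        units.append(rng.uniform(1, 2) * comps[0])
        labels.append({"PC1"})
    for _ in range(n_spc1):
        units.append(rng.uniform(1, 2) * comps[1])
        labels.append({"sPC1"})
    for _ in range(n_both):
        a = rng.uniform(1, 2)
        units.append(a * comps[0] + a * rng.uniform(0.8, 1.2) * comps[1])
        labels.append({"PC1", "sPC1"})
    for _ in range(n_none):
        units.append(np.zeros_like(comps[0]))
        labels.append(set())
    X = np.stack(units) + rng.normal(0, noise, (len(units),) + comps[0].shape)
    sdf = S.from_rates(X, DURATIONS, zscored=True)
    return sdf, [frozenset(l) for l in labels]


class TestReconstruction:
    def test_pure_component_unit_has_full_ev(self):
        comps = _orthonormal_components()
        traces = 2.5 * comps[0]
        _, ev = reconstruct_unit(np.array([2.5, 0.0]), comps, traces)
        assert ev == pytest.approx(100.0)

    def test_empty_subset_explains_nothing(self):
        comps = _orthonormal_components()
        traces = 2.5 * comps[0]
        _, ev = reconstruct_unit(np.array([2.5, 0.0]), comps, traces, subset=[])
        assert ev == 0.0

    def test_sixty_forty_variance_split(self):
        comps = _orthonormal_components()
        traces = np.sqrt(0.6) * comps[0] + np.sqrt(0.4) * comps[1]
        scores = np.array([np.sqrt(0.6), np.sqrt(0.4)])
        _, ev_first = reconstruct_unit(scores, comps, traces, subset=[0])
        _, ev_both = reconstruct_unit(scores, comps, traces)
        assert ev_first == pytest.approx(60.0, abs=1e-6)
        assert ev_both == pytest.approx(100.0, abs=1e-6)


class TestAngleRule:
    def _assign(self, scores, ev_threshold=0.0):
        comps = _orthonormal_components()
        traces = scores[0] * comps[0] + scores[1] * comps[1]
        return assign_category(
            0, np.asarray(scores, float), comps, traces, ["PC1", "sPC1"],
            "measurement", ev_threshold,
        )

    def test_equal_scores_make_both_contribute(self):
        assert self._assign(np.array([1.0, 1.0])).category == {"PC1", "sPC1"}

    def test_weak_second_component_is_dropped(self):
        # arctan(0.2) ~ 11.3 deg < 22.5 deg
        assert self._assign(np.array([1.0, 0.2])).category == {"PC1"}

    def test_threshold_ratio_is_tan_of_22_5_degrees(self):
        just_below = np.tan(np.radians(22.5)) - 1e-6
        just_above = np.tan(np.radians(22.5)) + 1e-6
        assert self._assign(np.array([1.0, just_below])).category == {"PC1"}
        assert self._assign(np.array([1.0, just_above])).category == {"PC1", "sPC1"}

    def test_low_ev_is_unrelated_regardless_of_scores(self):
        a = self._assign(np.array([5.0, 5.0]), ev_threshold=101.0)
        assert a.category == frozenset()

    def test_sign_flip_invariance(self):
        a = self._assign(np.array([1.0, 1.0]))
        b = self._assign(np.array([-1.0, 1.0]))
        assert {n for n in a.category} == {n for n in b.category}

    def test_raising_ev_threshold_is_monotone_toward_unrelated(self):
        scores = np.array([1.0, 0.8])
        cats = [self._assign(scores, thr).category for thr in (0, 50, 99.9, 100.1)]
        seen_unrelated = False
        for cat in cats:
            if seen_unrelated:
                assert cat == frozenset()
            seen_unrelated = seen_unrelated or cat == frozenset()


class TestCategorySpace:
    @pytest.mark.parametrize("n,expected", [(0, 1), (2, 4), (4, 16)])
    def test_power_set_size(self, n, expected):
        assert category_space_size(n) == expected


class TestPopulationCategorization:
    def test_planted_types_are_recovered(self):
        rng = np.random.default_rng(0)
        sdf, expected = _planted_population(rng)
        res = demixed_pca(sdf, n_time_pcs=1, n_stim_pcs=1)
        assigns = categorize_population(sdf, res, "measurement", ev_threshold=6.0)
        correct = np.mean([a.category == e for a, e in zip(assigns, expected)])
        assert correct >= 0.95

    def test_accuracy_degrades_gracefully_with_noise(self):
        accs = []
        for noise in (0.02, 0.2, 1.0):
            rng = np.random.default_rng(1)
            sdf, expected = _planted_population(rng, noise=noise)
            res = demixed_pca(sdf, n_time_pcs=1, n_stim_pcs=1)
            assigns = categorize_population(sdf, res, "measurement", ev_threshold=6.0)
            accs.append(np.mean([a.category == e for a, e in zip(assigns, expected)]))
        assert accs[0] > accs[-1]
        assert accs[0] >= 0.95

    def test_candidate_sets_per_phase(self):
        rng = np.random.default_rng(2)
        sdf, _ = _planted_population(rng)
        res = demixed_pca(sdf, n_time_pcs=3, n_stim_pcs=1)
        names_m, comps_m, _ = candidate_components(res, "measurement")
        names_r, comps_r, _ = candidate_components(res, "reproduction")
        assert names_m == ["PC1", "sPC1"] and comps_m.shape[0] == 2
        assert names_r == ["PC1", "PC2", "PC3", "sPC1"] and comps_r.shape[0] == 4

    def test_bootstrap_maximum_likelihood_labels_agree_on_clean_data(self):
        rng = np.random.default_rng(3)
        sdf, expected = _planted_population(rng, n_pc1=40, n_spc1=40, n_both=10, n_none=10)
        ml = maximum_likelihood_categories(sdf, "measurement", frac=0.3, runs=20, seed=4,
                                           ev_threshold=6.0)
        correct = np.mean([a.category == e for a, e in zip(ml, expected)])
        assert correct >= 0.9


class TestSurrogatesAndTransitions:
    def test_stimulus_tuned_category_is_enriched_over_surrogates(self):
        # shuffling traces across stimuli and cells preserves single-trace
        # shapes but destroys consistent stimulus ordering, so genuine
        # stimulus-tuned cells exceed the surrogate expectation
        rng = np.random.default_rng(5)
        sdf, _ = _planted_population(rng, n_pc1=30, n_spc1=40, n_both=5, n_none=25)
        report = chance_category_counts(sdf, "measurement", runs=60, seed=6,
                                        ev_threshold=6.0, n_time_pcs=1)
        spc1_only = frozenset({"sPC1"})
        assert report[spc1_only]["p"] < 0.05
        assert report[spc1_only]["direction"] == ">"

    def test_transition_table_conserves_units(self):
        rng = np.random.default_rng(7)
        sdf, expected = _planted_population(rng, n_pc1=10, n_spc1=10, n_both=5, n_none=5)
        res = demixed_pca(sdf, n_time_pcs=3, n_stim_pcs=1)
        am = categorize_population(sdf, res, "measurement", ev_threshold=6.0)
        ar = categorize_population(sdf, res, "reproduction", ev_threshold=6.0)
        table = transition_table(am, ar)
        assert sum(table["counts"].values()) == table["n_units"] == 30
        assert sum(table["activity_shares"].values()) == pytest.approx(1.0)

    def test_all_unrelated_population(self):
        assigns = [
            CategoryAssignment(unit=u, phase="measurement", category=frozenset(), ev=0.0)
            for u in range(4)
        ]
        table = transition_table(assigns, assigns)
        assert table["activity_shares"]["neither"] == 1.0
        assert table["counts"] == {(frozenset(), frozenset()): 4}

    def test_mismatched_unit_sets_are_rejected(self):
        a = [CategoryAssignment(0, "measurement", frozenset(), 0.0)]
        b = [CategoryAssignment(1, "reproduction", frozenset(), 0.0)]
        with pytest.raises(ValueError):
            transition_table(a, b)
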