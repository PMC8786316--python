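"""Generator tests: task statistics, observer, stereotypes, Poisson spikes."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pytest
from scipy import stats

from timepop.synthetic import (
    DEFAULT_GRID,
    ObserverParams,
    SessionConfig,
    StereotypeParams,
    StimulusGrid,
    generate_session,
    generate_spike_train,
    make_population,
    read_session_csv,
    read_session_hdf5,
    sample_stimuli,
    simulate_observer_trial,
    stereotype_rate,
    update_feedback,
    write_session_csv,
    write_session_hdf5,
)


class TestStimuli:
    def test_grid_is_the_seven_duration_grid(self):
        assert DEFAULT_GRID.durations == (3.0, 3.75, 4.5, 5.25, 6.0, 6.75, 7.5)
        assert DEFAULT_GRID.mean == pytest.approx(5.25)
        assert DEFAULT_GRID.spacing == pytest.approx(0.75)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            StimulusGrid(())
        with pytest.raises(ValueError):
            StimulusGrid((3.0, 2.0))
        with pytest.raises(ValueError):
            StimulusGrid((1.0, 2.0, 4.0))

    def test_samples_live_on_the_grid_and_are_reproducible(self):
        draws = sample_stimuli(DEFAULT_GRID, 1000, seed=3)
        assert set(np.unique(draws)) <= set(DEFAULT_GRID.durations)
        assert np.array_equal(draws, sample_stimuli(DEFAULT_GRID, 1000, seed=3))
        assert len(sample_stimuli(DEFAULT_GRID, 0, seed=3)) == 0

    def test_samples_are_uniform(self):
        draws = sample_stimuli(DEFAULT_GRID, 7000, seed=5)
        counts = [np.sum(draws == d) for d in DEFAULT_GRID.durations]
        assert stats.chisquare(counts).pvalue > 0.01


class TestObserver:
    def test_identity_observer_reproduces_exactly(self):
        p = ObserverParams(shrinkage=1.0, w_m=0.0, w_p=0.0)
        assert simulate_observer_trial(4.5, p, seed=0) == pytest.approx(4.5)

    def test_pure_prior_observer_returns_prior_mean(self):
        p = ObserverParams(shrinkage=0.0, w_m=0.0, w_p=0.0, prior_mean=5.25)
        for s in DEFAULT_GRID.durations:
            assert simulate_observer_trial(s, p, seed=0) == pytest.approx(5.25)

    def test_regression_slope_converges_to_shrinkage(self):
        p = ObserverParams(shrinkage=0.7, w_m=0.1, w_p=0.1)
        rng = np.random.default_rng(12)
        s_all, r_all = [], []
        for s in DEFAULT_GRID.durations:
            for _ in range(2000):
                s_all.append(s)
                r_all.append(simulate_observer_trial(s, p, rng))
        slope = stats.linregress(s_all, r_all).slope
        assert slope == pytest.approx(0.70, abs=0.02)

    def test_scalar_variability_with_production_noise_only(self):
        p = ObserverParams(shrinkage=1.0, w_m=0.0, w_p=0.1)
        rng = np.random.default_rng(4)
        cvs = []
        for s in (3.0, 7.5):
            r = [simulate_observer_trial(s, p, rng) for _ in range(4000)]
            cvs.append(np.std(r) / np.mean(r))
        assert cvs[0] == pytest.approx(cvs[1], rel=0.1)
        assert cvs[0] == pytest.approx(0.1, rel=0.1)


class TestFeedback:
    @pytest.mark.parametrize(
        "r_factor,k,expected",
        [
            (1.0, 0.15, (True, 0.12)),
            (2.0, 0.15, (False, 0.18)),
            (1.0, 0.02, (True, 0.0)),
        ],
    )
    def test_tolerance_update_rule(self, r_factor, k, expected):
        s = 5.0
        in_out, k_next = update_feedback(r_factor * s, s, k)
        assert in_out == expected[0]
        assert k_next == pytest.approx(expected[1])

    def test_boundary_reproduction_is_rewarded(self):
        assert update_feedback(1.15 * 4.0, 4.0, 0.15)[0]
        assert not update_feedback(1.151 * 4.0, 4.0, 0.15)[0]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.floats(0.1, 20.0),
        st.floats(0.1, 20.0),
        st.floats(0.0, 1.0),
    )
    def test_update_is_consistent_and_bounded(self, r, s, k):
        in_out, k_next = update_feedback(r, s, k)
        assert in_out == ((1 - k) * s <= r <= (1 + k) * s)
        assert k_next >= 0.0
        assert abs(k_next - k) <= 0.03 + 1e-12


class TestStereotypes:
    def test_ramp_to_threshold_reaches_same_level_at_every_duration(self):
        p = StereotypeParams(kind="ramp_to_threshold_up", baseline=1.0, amplitude=8.0)
        for s in DEFAULT_GRID.durations:
            assert stereotype_rate(p, s, s) == pytest.approx(9.0)

    def test_linear_increasing_arithmetic(self):
        p = StereotypeParams(kind="linear_increasing", baseline=1.0, slope=2.0)
        assert stereotype_rate(p, 5.0, 0.0) == pytest.approx(1.0)
        assert stereotype_rate(p, 5.0, 3.0) == pytest.approx(7.0)

    def test_phasic_profiles_peak_where_declared(self):
        pa = StereotypeParams(kind="phasic_absolute", baseline=0.0, amplitude=5.0, peak_time=2.0)
        pr = StereotypeParams(kind="phasic_relative", baseline=0.0, amplitude=5.0, phase=0.5, peak_width=0.2)
        t = np.linspace(0, 6.0, 601)
        assert t[np.argmax(stereotype_rate(pa, 6.0, t))] == pytest.approx(2.0, abs=0.02)
        assert t[np.argmax(stereotype_rate(pr, 6.0, t))] == pytest.approx(3.0, abs=0.02)

    def test_stimulus_constant_is_ordered_by_duration(self):
        p = StereotypeParams(kind="stimulus_constant", baseline=10.0, amplitude=5.0)
        rates = [stereotype_rate(p, s, s / 2) for s in DEFAULT_GRID.durations]
        assert np.all(np.diff(rates) > 0)

    def test_time_outside_interval_is_a_domain_error(self):
        p = StereotypeParams(kind="linear_increasing")
        with pytest.raises(ValueError):
            stereotype_rate(p, 3.0, 3.5)

    def test_rates_are_rectified(self):
        p = StereotypeParams(kind="ramp_to_threshold_down", baseline=0.0, amplitude=-5.0)
        assert stereotype_rate(p, 4.0, 0.0) == 0.0


class TestSpikeGenerator:
    def test_zero_rate_gives_empty_train(self):
        train = generate_spike_train(lambda t: np.zeros_like(np.asarray(t)), 5.0, seed=0)
        assert len(train) == 0

    def test_homogeneous_counts_match_poisson_mean(self):
        rng = np.random.default_rng(7)
        counts = [
            len(generate_spike_train(lambda t: np.full(np.shape(t), 10.0), 5.0, rng))
            for _ in range(1000)
        ]
        # mean count 50, SE = sqrt(50/1000); allow 3 SE
        assert np.mean(counts) == pytest.approx(50.0, abs=0.7)

    def test_negative_rate_is_rejected(self):
        with pytest.raises(ValueError):
            generate_spike_train(lambda t: np.asarray(t) - 10.0, 5.0, seed=0)

    def test_time_rescaling_of_ramp_rate(self):
        # Lambda(t) = t + t^2 for rate 1 + 2t; transformed ISIs ~ Exp(1)
        rng = np.random.default_rng(21)
        spikes = generate_spike_train(lambda t: 1.0 + 2.0 * np.asarray(t), 20.0, rng)
        rescaled = spikes + spikes**2
        isis = np.diff(rescaled)
        assert stats.kstest(isis, "expon").pvalue > 0.01


class TestSession:
    def test_shapes_and_determinism(self):
        cfg = SessionConfig(n_trials=12, n_units=5, seed=3)
        trials, spikes = generate_session(cfg)
        assert len(trials) == 12
        assert spikes.n_units == 5 and spikes.n_trials == 12
        trials2, spikes2 = generate_session(cfg)
        assert [t.reproduction for t in trials] == [t.reproduction for t in trials2]
        for u in range(5):
            for i in range(12):
                assert np.array_equal(spikes.trains[u][i], spikes2.trains[u][i])

    def test_phase_markers_match_stimulus_and_reproduction(self):
        cfg = SessionConfig(n_trials=10, n_units=2, seed=9)
        trials, spikes = generate_session(cfg)
        for i, trial in enumerate(trials):
            t0, t1, t2, t3 = spikes.phases[i]
            assert t1 - t0 == pytest.approx(trial.stimulus)
            assert t3 - t2 == pytest.approx(trial.reproduction)
            assert cfg.gap_range[0] <= t2 - t1 <= cfg.gap_range[1]

    def test_tolerance_walk_respects_floor_and_step(self):
        cfg = SessionConfig(n_trials=80, n_units=1, k0=0.05, seed=5)
        trials, _ = generate_session(cfg)
        ks = [t.tolerance for t in trials]
        assert min(ks) >= 0.0
        for prev, nxt, rew in zip(ks, ks[1:], [t.reward for t in trials]):
            if rew:
                assert nxt == pytest.approx(max(0.0, prev - 0.03))
            else:
                assert nxt == pytest.approx(prev + 0.03)

    def test_competent_observer_earns_rewards(self):
        cfg = SessionConfig(
            n_trials=200,
            n_units=1,
            observer=ObserverParams(shrinkage=0.95, w_m=0.02, w_p=0.02),
            k0=0.2,
            seed=2,
        )
        trials, _ = generate_session(cfg)
        assert np.mean([t.reward for t in trials]) > 0.5

    def test_linear_units_end_rate_increases_with_stimulus(self):
        pop = [
            StereotypeParams(kind="linear_increasing", baseline=1.0, slope=s)
            for s in (1.5, 2.5, 3.5)
        ]
        cfg = SessionConfig(n_trials=140, n_units=3, rate_noise_sd=0.0, seed=17)
        trials, spikes = generate_session(cfg, population=pop)
        stimuli = np.unique(spikes.stimuli)
        for u in range(3):
            end_rates = []
            for s in stimuli:
                idx = np.flatnonzero(spikes.stimuli == s)
                counts = [
                    np.sum((spikes.trains[u][i] >= s - 1.0) & (spikes.trains[u][i] <= s))
                    for i in idx
                ]
                end_rates.append(np.mean(counts))
            r = stats.pearsonr(stimuli, end_rates).statistic
            assert r > 0.8

    def test_bad_mixture_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            make_population(10, {"linear_increasing": 0.5}, seed=0)
        with pytest.raises(ValueError):
            make_population(10, {"not_a_kind": 1.0}, seed=0)


class TestSessionIO:
    def test_hdf5_roundtrip(self, small_session, tmp_path):
        _, trials, spikes = small_session
        path = tmp_path / "session.h5"
        write_session_hdf5(path, trials, spikes)
        trials2, spikes2 = read_session_hdf5(path)
        assert [t.stimulus for t in trials] == [t.stimulus for t in trials2]
        assert np.allclose(spikes.phases, spikes2.phases)
        assert np.array_equal(spikes.trains[2][3], spikes2.trains[2][3])

    def test_csv_roundtrip(self, small_session, tmp_path):
        _, trials, spikes = small_session
        write_session_csv(tmp_path, trials, spikes)
        trials2, spikes2 = read_session_csv(tmp_path)
        assert [t.reward for t in trials] == [t.reward for t in trials2]
        assert np.allclose(
            np.sort(spikes.trains[0][0]), np.sort(spikes2.trains[0][0])
        )
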