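"""Generator tests: schedules, coupled signals, structural nets, recall sets."""

import numpy as np
import pytest
from scipy import stats

from stimnet.coherence import DEFAULT_BANDS, band_adjacency, multitaper_coherence
from stimnet.control import controllability_profile
from stimnet.errors import GenerationError, InvalidConfigError, NyquistError
from stimnet.schedule import ParameterGrid, draw_trial_schedule
from stimnet.synth import (
    default_ground_truth,
    inject_stim_effects,
    synth_coupled_timeseries,
    synth_recall_features,
    synth_session,
    synth_structural_network,
)


class TestTrialSchedule:
    def test_grid_enumerates_45_combinations(self):
        grid = ParameterGrid()
        combos = grid.combinations()
        assert grid.n_combinations == 45
        assert len(set(combos)) == 45

    def test_zero_trials_gives_empty_schedule(self):
        sched = draw_trial_schedule(n_trials=0, seed=0)
        assert sched.trials == []
        assert sched.baseline_span == (0.0, 30.0)

    def test_draws_are_uniform_over_the_grid(self):
        # oracle: exact multinomial expectation of 100 draws per cell
        n = 4500
        sched = draw_trial_schedule(n_trials=n, seed=7)
        combos = ParameterGrid().combinations()
        counts = {c: 0 for c in combos}
        for t in sched.trials:
            counts[(t.pulse_frequency, t.amplitude, t.duration)] += 1
        observed = np.array(list(counts.values()))
        assert (observed > 0).all(), "every combination should be observed"
        p = stats.chisquare(observed).pvalue
        assert p > 0.01

    def test_isi_and_ordering_invariants(self):
        sched = draw_trial_schedule(n_trials=50, seed=3)
        prev_offset = sched.baseline_span[1]
        for t in sched.trials:
            assert 2.75 <= t.onset - prev_offset <= 3.25
            prev_offset = t.offset

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidConfigError):
            ParameterGrid(pulse_frequencies=())

    def test_reproducible_under_fixed_seed(self):
        a = draw_trial_schedule(n_trials=20, seed=5)
        b = draw_trial_schedule(n_trials=20, seed=5)
        assert [t.onset for t in a.trials] == [t.onset for t in b.trials]


def _mean_band_coherence(x, y, fs, lo, hi):
    freqs, coh = multitaper_coherence(x, y, fs)
    return float(np.nanmean(coh[(freqs >= lo) & (freqs <= hi)]))


@pytest.fixture(scope="module")
def noise_floor_mc():
    """Monte-Carlo distribution of mean in-band coherence between
    independent white-noise channels (the 8-taper estimator's bias floor)."""
    rng = np.random.default_rng(2024)
    vals = []
    for _ in range(1000):
        x, y = rng.standard_normal((2, 250))
        vals.append(_mean_band_coherence(x, y, 500.0, 5.0, 15.0))
    return np.array(vals)


class TestCoupledTimeseries:
    def test_full_coupling_gives_near_unit_coherence(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        rec = synth_coupled_timeseries(2, 500, 0.5, C, noise_sd=0.0, seed=0)
        nets = band_adjacency(rec.signal, 500)
        for band in DEFAULT_BANDS:
            assert nets[band.name].A[0, 1] >= 0.99

    def test_zero_coupling_matches_estimator_bias_floor(self, noise_floor_mc):
        # with no shared components and no band structure the channels are
        # independent noise; their coherence must sit on the white-noise
        # Monte-Carlo floor of the 8-taper estimator
        C = np.zeros((2, 2))
        vals = []
        for seed in range(100):
            rec = synth_coupled_timeseries(
                2, 500, 0.5, C, noise_sd=1.0, band_amplitude=0.0, seed=seed
            )
            vals.append(
                _mean_band_coherence(rec.signal[0], rec.signal[1], 500, 5, 15)
            )
        se = noise_floor_mc.std() * np.sqrt(
            1 / len(vals) + 1 / len(noise_floor_mc)
        )
        assert abs(np.mean(vals) - noise_floor_mc.mean()) < 2 * se

    def test_zero_coupling_narrowband_floor_is_elevated_but_bounded(self):
        # uncoupled narrowband components concentrate power in few
        # resolution bandwidths, so their bias floor exceeds the white-noise
        # 1/k floor; it must still stay well below weak true coupling
        C = np.zeros((2, 2))
        vals = []
        for seed in range(50):
            rec = synth_coupled_timeseries(2, 500, 0.5, C, noise_sd=1.0, seed=seed)
            vals.append(
                _mean_band_coherence(rec.signal[0], rec.signal[1], 500, 5, 15)
            )
        assert 1 / 8 < np.mean(vals) < 0.3

    def test_coherence_increases_monotonically_with_coupling(self):
        means = []
        for c in (0.0, 0.5, 0.9):
            C = np.array([[0.0, c], [c, 0.0]])
            vals = [
                _mean_band_coherence(
                    *synth_coupled_timeseries(
                        2, 500, 0.5, C, noise_sd=0.5, seed=s
                    ).signal,
                    500,
                    5,
                    15,
                )
                for s in range(100)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(NyquistError):
            synth_coupled_timeseries(2, 200, 1.0, np.zeros((2, 2)))

    def test_reproducible_under_fixed_seed(self):
        C = np.full((3, 3), 0.3)
        np.fill_diagonal(C, 0)
        a = synth_coupled_timeseries(3, 500, 1.0, C, seed=9)
        b = synth_coupled_timeseries(3, 500, 1.0, C, seed=9)
        np.testing.assert_array_equal(a.signal, b.signal)


class TestInjectEffects:
    def test_null_effects_leave_recording_bitwise_identical(self):
        labels = [f"ch{i:02d}" for i in range(4)]
        truth = default_ground_truth(labels, seed=1)
        sched = draw_trial_schedule(n_trials=5, seed=1, stim_pair=(labels[0], labels[1]))
        rec = synth_coupled_timeseries(
            4, 500, sched.end_time + 2.0, truth.coupling, seed=2, labels=labels
        )
        out = inject_stim_effects(rec, sched, truth)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_samples_outside_response_windows_unchanged(self):
        labels = [f"ch{i:02d}" for i in range(4)]
        truth = default_ground_truth(
            labels, seed=1, effect_gain={"alpha_theta": 0.3}
        )
        sched = draw_trial_schedule(n_trials=5, seed=1, stim_pair=(labels[0], labels[1]))
        rec = synth_coupled_timeseries(
            4, 500, sched.end_time + 2.0, truth.coupling, seed=2, labels=labels
        )
        out = inject_stim_effects(rec, sched, truth)
        changed = np.any(out.signal != rec.signal, axis=0)
        spans = []
        for t in sched.trials:
            start = int(round(t.offset * 500)) + 50
            spans.append((start, start + 500))
        outside = np.ones(rec.n_samples, dtype=bool)
        for a, b in spans:
            outside[a:b] = False
        assert not changed[outside].any()
        assert changed[~outside].any()

    def test_alpha_gain_raises_downstream_delta_mean_k(self):
        # parameter recovery at the single-session scale: the pipeline's
        # alpha/theta stim-vs-surrogate contrast carries the planted sign
        # in nearly every seeded session
        from stimnet.pipeline import RunConfig, run_session

        cfg = RunConfig(n_channels=6, n_trials=15)
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            r = run_session(
                cfg,
                seed=seed,
                truth_kwargs=dict(
                    effect_gain={"alpha_theta": 0.35},
                    routing={"alpha_theta": "stim_routed"},
                ),
            )
            diff = r.session_mean("alpha_theta", "delta_mean_k") - r.session_mean(
                "alpha_theta", "delta_mean_k", "surrogate"
            )
            hits += diff > 0
        assert hits >= int(0.9 * n_rep)


class TestStructuralNetwork:
    def test_ring_lattice_has_equal_strengths(self):
        net = synth_structural_network(12, topology="ring", seed=0)
        k = net.S.sum(axis=1)
        np.testing.assert_allclose(k, k[0])

    def test_symmetry_and_zero_diagonal(self):
        for topo in ("heavy_tailed", "lattice", "ring"):
            net = synth_structural_network(30, topology=topo, seed=1)
            np.testing.assert_array_equal(net.S, net.S.T)
            np.testing.assert_array_equal(np.diag(net.S), 0.0)
            assert (net.S >= 0).all()

    def test_heavy_tailed_strength_anticorrelates_with_phi(self):
        net = synth_structural_network(200, topology="heavy_tailed", seed=3)
        prof = controllability_profile(net)
        rho = stats.spearmanr(prof.structural_strength, prof.phi).statistic
        assert rho < 0

    def test_hemisphere_split_and_bad_input(self):
        net = synth_structural_network(21, seed=0, hemisphere_split=True)
        assert net.hemisphere.count("L") == 10
        assert net.hemisphere.count("R") == 11
        with pytest.raises(InvalidConfigError):
            synth_structural_network(1)


class TestRecallFeatures:
    def test_zero_weights_give_chance_auc(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        X, y = synth_recall_features(400, 4, seed=0)
        clf = LogisticRegression(max_iter=500).fit(X[:200], y[:200])
        auc = roc_auc_score(y[200:], clf.decision_function(X[200:]))
        n1, n2 = y[200:].sum(), (1 - y[200:]).sum()
        se = np.sqrt((n1 + n2 + 1) / (12 * n1 * n2))  # Hanley-McNeil null SE
        assert abs(auc - 0.5) < 2 * se

    def test_planted_weight_sign_recovered(self):
        from sklearn.linear_model import LogisticRegression

        w = np.zeros(4 * 8)
        w[5] = 2.0
        hits = 0
        for seed in range(100):
            X, y = synth_recall_features(100, 4, planted_weights=w, seed=seed)
            clf = LogisticRegression(max_iter=500).fit(X, y)
            hits += clf.coef_.ravel()[5] > 0
        assert hits >= 95

    def test_auc_decreases_with_noise(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        w = np.full(2 * 8, 0.5)
        aucs = []
        for noise in (0.5, 4.0, 32.0):
            vals = []
            for seed in range(10):
                X, y = synth_recall_features(
                    300, 2, planted_weights=w, noise_sd=noise, seed=seed
                )
                clf = LogisticRegression(max_iter=500).fit(X[:150], y[:150])
                vals.append(roc_auc_score(y[150:], clf.decision_function(X[150:])))
            aucs.append(np.mean(vals))
        assert aucs[0] > aucs[1] > aucs[2]
        assert aucs[2] < 0.6

    def test_validation_errors(self):
        with pytest.raises(InvalidConfigError):
            synth_recall_features(10, 4)
        with pytest.raises(InvalidConfigError):
            synth_recall_features(50, 4, planted_weights=np.ones(3))


def test_session_generator_is_deterministic():
    rec1, sched1, truth1 = synth_session(n_channels=4, n_trials=5, seed=11)
    rec2, sched2, truth2 = synth_session(n_channels=4, n_trials=5, seed=11)
    np.testing.assert_array_equal(rec1.signal, rec2.signal)
    assert [t.onset for t in sched1.trials] == [t.onset for t in sched2.trials]
    np.testing.assert_array_equal(
        truth1.coupling["beta"], truth2.coupling["beta"]
    )


def test_recall_generation_error_on_exhausted_retries():
    with pytest.raises(GenerationError):
        synth_recall_features(20, 2, seed=0, max_retries=0)
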