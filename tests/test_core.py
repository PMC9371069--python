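"""Spatial-filter estimation and distance-based classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itdma import (
    EEGTrial,
    TrainingSet,
    classify,
    compute_power_Q,
    compute_scatter_P,
    decision_distances,
    fit,
    generate_trial,
    solve_spatial_filter,
)
from itdma.core import load_model, save_model
from itdma.sim import default_mixing
from itdma import MixingModel, StimulusConfig, generate_dataset


class TestScatterP:
    def test_two_trials_ordered_pairs_double_count(self, rng):
        a, b = rng.normal(size=(2, 3, 12))
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        d = ac - bc
        np.testing.assert_allclose(compute_scatter_P([a, b]), 2 * d @ d.T, atol=1e-12)

    def test_identical_trials_give_zero(self, rng):
        a = rng.normal(size=(4, 20))
        np.testing.assert_allclose(compute_scatter_P([a, a, a]), 0.0, atol=1e-10)

    def test_closed_form_matches_double_loop(self, rng):
        # brute-force oracle: explicit ordered-pair double sum
        mats = [rng.normal(size=(4, 20)) for _ in range(5)]
        P = compute_scatter_P(mats)
        cen = [m - m.mean(axis=1, keepdims=True) for m in mats]
        brute = np.zeros((4, 4))
        for m1 in range(5):
            for m2 in range(5):
                if m1 != m2:
                    d = cen[m1] - cen[m2]
                    brute += d @ d.T
        assert np.abs(P - brute).max() < 1e-10

    def test_needs_two_trials(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            compute_scatter_P([rng.normal(size=(3, 10))])

    def test_shape_mismatch_refused(self, rng):
        with pytest.raises(ValueError, match="shape"):
            compute_scatter_P([rng.normal(size=(3, 10)), rng.normal(size=(3, 12))])


class TestPowerQ:
    def test_white_unit_variance_approaches_identity(self, rng):
        m = rng.standard_normal((4, 200_000))
        Q = compute_power_Q([m])
        assert np.abs(Q - np.eye(4)).max() < 0.02

    def test_constant_trial_gives_zero(self):
        m = np.full((3, 50), 7.5)
        np.testing.assert_allclose(compute_power_Q([m]), 0.0, atol=1e-12)

    def test_additive_over_trials(self, rng):
        m = rng.normal(size=(3, 40))
        np.testing.assert_allclose(
            compute_power_Q([m, m, m]), 3 * compute_power_Q([m]), atol=1e-10
        )

    def test_single_sample_refused(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            compute_power_Q([np.ones((3, 1))])


class TestSolveSpatialFilter:
    def test_diagonal_case_selects_smallest_ratio(self):
        f = solve_spatial_filter(np.diag([3.0, 1.0, 2.0]), np.eye(3))
        np.testing.assert_allclose(np.abs(f.w), [0, 1, 0], atol=1e-7)
        assert f.objective_value == pytest.approx(1.0)
        assert f.w[1] > 0  # sign canonicalization

    def test_scalar_case(self):
        f = solve_spatial_filter(np.array([[6.0]]), np.array([[4.0]]))
        assert f.w[0] == pytest.approx(1 / 2.0, rel=1e-6)
        assert f.objective_value == pytest.approx(6.0 / 4.0, rel=1e-6)

    def test_constraint_satisfied(self, rng):
        A = rng.normal(size=(5, 5))
        B = rng.normal(size=(5, 5))
        P, Q = A @ A.T, B @ B.T + 0.5 * np.eye(5)
        f = solve_spatial_filter(P, Q)
        assert f.w @ Q @ f.w == pytest.approx(1.0, abs=1e-6)

    def test_matches_random_search_oracle(self, rng):
        # brute-force Rayleigh-quotient minimum over 1e5 random directions
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            B = rng.normal(size=(3, 3))
            P = A @ A.T + 0.5 * np.eye(3)
            Q = B @ B.T + 0.5 * np.eye(3)
            f = solve_spatial_filter(P, Q)
            V = rng.normal(size=(100_000, 3))
            ratios = np.einsum("ij,jk,ik->i", V, P, V) / np.einsum(
                "ij,jk,ik->i", V, Q, V
            )
            rmin = ratios.min()
            assert f.objective_value <= rmin * (1 + 1e-9)
            assert rmin <= f.objective_value * 1.01

    def test_powerless_q_refused(self):
        with pytest.raises(np.linalg.LinAlgError, match="power"):
            solve_spatial_filter(np.eye(2), np.zeros((2, 2)))


class TestFit:
    def test_minimal_two_trial_set(self, rng):
        groups = [
            [EEGTrial(rng.normal(size=(4, 30)), 250.0, list("abcd")) for _ in range(2)]
            for _ in range(2)
        ]
        model = fit(TrainingSet(groups, 250.0))
        assert model.ensemble.shape == (4, 2)
        assert len(model.templates) == 2

    def test_templates_are_exact_trial_means(self, noisy_set):
        model = fit(noisy_set)
        for i in range(noisy_set.n_targets):
            np.testing.assert_array_equal(
                model.templates[i], np.mean(noisy_set.matrices(i + 1), axis=0)
            )

    def test_filter_constraint_against_target_Q(self, noisy_set):
        model = fit(noisy_set)
        for i in range(noisy_set.n_targets):
            Q = compute_power_Q(noisy_set.matrices(i + 1))
            w = model.ensemble[:, i]
            assert w @ Q @ w == pytest.approx(1.0, abs=1e-6)

    def test_filtered_trials_more_consistent_than_any_channel(self, noisy_set):
        # spatial combination should beat the best single channel at
        # inter-trial agreement (that is the training objective)
        model = fit(noisy_set)

        def mean_pair_corr(sigs):
            cs = [
                np.corrcoef(sigs[a], sigs[b])[0, 1]
                for a in range(len(sigs))
                for b in range(a + 1, len(sigs))
            ]
            return float(np.mean(cs))

        mats = noisy_set.matrices(1)
        filtered = mean_pair_corr([model.ensemble[:, 0] @ m for m in mats])
        per_channel = max(
            mean_pair_corr([m[j] for m in mats]) for j in range(noisy_set.n_channels)
        )
        assert filtered > per_channel

    def test_unequal_trial_lengths_refused(self, rng):
        a = EEGTrial(rng.normal(size=(3, 30)), 250.0, list("abc"))
        b = EEGTrial(rng.normal(size=(3, 40)), 250.0, list("abc"))
        with pytest.raises(Exception, match="shape"):
            TrainingSet([[a, b], [a, a]], 250.0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, noisy_set, c):
        # rescaling all trials of a target rescales w by 1/c (unit power)
        # and leaves decisions on equally rescaled test data unchanged
        base = fit(noisy_set)
        scaled_set = TrainingSet(
            [[t.copy_with(t.data * c) for t in g] for g in noisy_set.trials],
            noisy_set.fs,
        )
        scaled = fit(scaled_set)
        np.testing.assert_allclose(scaled.ensemble * c, base.ensemble, rtol=1e-5)
        probe = noisy_set.trials[1][0].data
        assert classify(base, probe) == classify(scaled, probe * c)


class TestDecision:
    def toy_model(self):
        groups = [
            [
                EEGTrial(np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 1.0]]), 10.0, ["a", "b"]),
                EEGTrial(np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]), 10.0, ["a", "b"]),
            ],
            [
                EEGTrial(np.array([[0.0, -1.0, 1.0], [1.0, 0.0, 2.0]]), 10.0, ["a", "b"]),
                EEGTrial(np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 2.0]]), 10.0, ["a", "b"]),
            ],
        ]
        return fit(TrainingSet(groups, 10.0))

    def test_hand_computed_toy_distances(self):
        # oracle: Frobenius-norm arithmetic spelled out with scalar loops
        model = self.toy_model()
        S = np.array([[0.5, 0.0, 1.0], [1.0, 0.5, 2.0]])
        E = model.ensemble
        expected = []
        for tmpl in model.templates:
            acc = 0.0
            for col in range(3):
                for row in range(2):
                    proj_s = sum(E[ch, row] * S[ch, col] for ch in range(2))
                    proj_t = sum(E[ch, row] * tmpl[ch, col] for ch in range(2))
                    acc += (proj_s - proj_t) ** 2
            expected.append(acc ** 0.5)
        np.testing.assert_allclose(decision_distances(model, S), expected, rtol=1e-12)

    def test_template_has_zero_self_distance(self, noisy_set):
        model = fit(noisy_set)
        d = decision_distances(model, model.templates[1])
        assert d[1] == pytest.approx(0.0, abs=1e-10)
        assert d[0] > 0 and d[2] > 0
        assert classify(model, model.templates[1]) == 2

    def test_zero_signal_distance_is_template_norm(self, noisy_set):
        model = fit(noisy_set)
        d = decision_distances(model, np.zeros_like(model.templates[0]))
        for i, tmpl in enumerate(model.templates):
            assert d[i] == pytest.approx(
                np.linalg.norm(model.ensemble.T @ tmpl, ord="fro")
            )

    def test_exact_tie_breaks_to_lowest_index(self):
        model = self.toy_model()
        # equidistant point: mirror templates through their midpoint axis
        model.templates[1] = model.templates[0].copy()
        S = np.ones((2, 3))
        assert classify(model, S) == 1

    def test_shape_mismatch_names_lengths(self, noisy_set):
        model = fit(noisy_set)
        with pytest.raises(ValueError, match="channels"):
            decision_distances(model, np.zeros((6, 17)))

    def test_high_snr_synthetic_trial_recovered(self, noisy_set):
        model = fit(noisy_set)
        trial = generate_trial(
            default_mixing(snr_db=5.0), StimulusConfig(), 2, 1.0, 250.0, seed=99
        )
        assert classify(model, trial) == 2


class TestLimits:
    def test_noiseless_loocv_is_perfect(self, noiseless_set):
        from itdma import loocv_accuracy

        assert loocv_accuracy(noiseless_set, "itdma").accuracy == 1.0

    def test_pure_noise_is_at_chance(self):
        from itdma import loocv_accuracy

        mix = MixingModel(r1=np.zeros(6), r2=np.ones(6))
        training, _ = generate_dataset(mix, n_t=10, duration_s=0.5, seed=11)
        acc = loocv_accuracy(training, "itdma").accuracy
        # binomial 95% band around 1/3 with n = 30 decisions
        half = 1.96 * np.sqrt((1 / 3) * (2 / 3) / 30)
        assert abs(acc - 1 / 3) <= half


class TestSerialization:
    def test_model_round_trip(self, tmp_path, noisy_set):
        model = fit(noisy_set)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_array_equal(back.ensemble, model.ensemble)
        for a, b in zip(back.templates, model.templates):
            np.testing.assert_array_equal(a, b)
        assert back.fs == model.fs
        probe = noisy_set.trials[0][0]
        assert classify(back, probe) == classify(model, probe)
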