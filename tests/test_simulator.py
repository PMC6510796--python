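"""Gaussian clusters, perturbation schedules, and the jump simulator."""

import numpy as np
import pytest

from motiondecomp import (
    AdaptationParams,
    GaussianTaskSpec,
    PerturbationSchedule,
    detect_release,
    make_schedule,
    sample_gaussian_tasks,
    simulate_experiment,
    trajectory_features,
)
from motiondecomp.kinematics import back_position, back_velocity, parabolic_height
from motiondecomp.simulate import HEIGHT_SCALE, Q_STAND, default_windows


class TestGaussianTasks:
    def test_centered_cluster_constraint_level(self):
        spec = GaussianTaskSpec(means=((0.0, 0.0),), n_per_task=100_000,
                                seed=1)
        x, _ = sample_gaussian_tasks(spec)
        diff = x.values[:, 0] - x.values[:, 1]
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se

    def test_projected_variance_matches_analytic(self):
        # Var(X1 - X2) = 0.75 + 0.75 - 2*0.7 = 0.1
        spec = GaussianTaskSpec(means=((0.0, 0.0),), n_per_task=100_000,
                                seed=2)
        x, _ = sample_gaussian_tasks(spec)
        diff = x.values[:, 0] - x.values[:, 1]
        var = diff.var(ddof=1)
        se = var * np.sqrt(2 / (diff.size - 1))
        assert abs(var - 0.1) < 3 * se

    def test_deterministic_given_seed(self):
        a, la = sample_gaussian_tasks(GaussianTaskSpec(seed=9))
        b, lb = sample_gaussian_tasks(GaussianTaskSpec(seed=9))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(la, lb)

    def test_non_positive_definite_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            sample_gaussian_tasks(GaussianTaskSpec(cov=((1.0, 2.0),
                                                        (2.0, 1.0))))


class TestSchedules:
    def test_constant_pattern(self):
        p = make_schedule(PerturbationSchedule(kind="constant"))
        assert p.size == 45
        assert (p != 0).sum() == 30
        np.testing.assert_allclose(p[:5], 0)
        np.testing.assert_allclose(p[5:20], 0.05)
        np.testing.assert_allclose(p[20:30], 0)
        np.testing.assert_allclose(p[30:45], -0.05)

    def test_constant_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="45"):
            make_schedule(PerturbationSchedule(kind="constant", n_trials=40))

    @pytest.mark.parametrize("n,expected", [(95, 19), (96, 19), (100, 20)])
    def test_probe_one_perturbation_per_complete_block(self, n, expected):
        p = make_schedule(PerturbationSchedule(kind="probe", n_trials=n,
                                               seed=4))
        nz = np.flatnonzero(p)
        assert nz.size == expected
        for b in range(n // 5):
            block = p[5 * b : 5 * b + 5]
            assert (block != 0).sum() == 1
            assert abs(block[block != 0][0]) == 0.05
        # signs balanced up to parity
        assert abs((p > 0).sum() - (p < 0).sum()) <= 1

    def test_gradual_ramp_then_hold(self):
        p = make_schedule(PerturbationSchedule(kind="gradual", sign=-1))
        assert p.size == 30
        np.testing.assert_allclose(p[:10], 0)
        np.testing.assert_allclose(p[10:20],
                                   -0.05 * np.arange(1, 11) / 10)
        np.testing.assert_allclose(p[20:], -0.05)

    def test_none_is_all_zero(self):
        assert not make_schedule(
            PerturbationSchedule(kind="none", n_trials=12)).any()

    def test_deterministic_given_seed(self):
        s = PerturbationSchedule(kind="probe", seed=77)
        np.testing.assert_array_equal(make_schedule(s), make_schedule(s))


class TestSimulatedExperiment:
    def test_no_learning_no_noise_constant_height(self):
        adapt = AdaptationParams(eta=1e-9, exec_noise_rel=0.0,
                                 exec_noise_irr=0.0)
        exp = simulate_experiment(PerturbationSchedule(kind="none"),
                                  adapt=adapt, targets=0.5, seed=0)
        assert np.ptp(exp.heights) < 1e-9

    def test_constant_perturbation_geometric_convergence(self):
        # zero noise: the height approaches target - p with ratio (1 - eta)
        eta = 0.5
        adapt = AdaptationParams(eta=eta, exec_noise_rel=0.0,
                                 exec_noise_irr=0.0)
        p = np.full(25, 0.05)
        # the linear height model makes the recursion exact; the parabolic
        # model adds a small curvature correction to the contraction ratio
        exp = simulate_experiment(p, adapt=adapt, targets=0.5, seed=0,
                                  height_model="linear")
        resid = exp.heights - (0.5 - 0.05)
        ratios = resid[1:10] / resid[:9]
        np.testing.assert_allclose(ratios, 1 - eta, rtol=1e-8)
        exp_fk = simulate_experiment(p, adapt=adapt, targets=0.5, seed=0)
        resid = exp_fk.heights - (0.5 - 0.05)
        np.testing.assert_allclose(resid[1:10] / resid[:9], 1 - eta,
                                   rtol=0.1)

    def test_learning_rate_recovered_by_regression(self):
        # oracle: first-order fit of height changes on previous-trial error
        eta = 0.3
        adapt = AdaptationParams(eta=eta, exec_noise_rel=0.0,
                                 exec_noise_irr=0.0)
        sched = PerturbationSchedule(kind="probe", n_trials=500, seed=5)
        exp = simulate_experiment(sched, adapt=adapt, targets=0.5, seed=5)
        dk = np.diff(exp.heights)
        e = (exp.targets - exp.displayed)[:-1]
        slope = np.polyfit(e, dk, 1)[0]
        assert slope == pytest.approx(eta, rel=0.10)

    def test_heights_consistent_with_forward_kinematics(self):
        exp = simulate_experiment(PerturbationSchedule(kind="probe"), seed=3)
        k0_abs = back_position(Q_STAND, exp.links)
        x = trajectory_features(exp.trajectories, candidate=1,
                                n_frames=exp.n_window_frames)
        f = exp.n_window_frames
        q_rel = x.values[:, [i * f + f - 1 for i in range(4)]]
        qd_rel = x.values[:, [4 * f + i * f + f - 1 for i in range(4)]]
        for t in range(x.n_trials):
            p = back_position(q_rel[t], exp.links)
            v = back_velocity(q_rel[t], qd_rel[t], exp.links)
            k = (parabolic_height(p, v, exp.links.g) - k0_abs) / HEIGHT_SCALE
            assert abs(k - exp.heights[t]) < 1e-10

    def test_release_detection_recovers_planted_frame(self):
        exp = simulate_experiment(PerturbationSchedule(kind="none"), seed=6)
        for traj in exp.trajectories[:5]:
            assert detect_release(traj.toe_y) == exp.release_frame

    def test_features_match_trajectory_windows(self):
        exp = simulate_experiment(PerturbationSchedule(kind="none"), seed=8)
        x = trajectory_features(exp.trajectories, candidate=1,
                                n_frames=exp.n_window_frames)
        np.testing.assert_allclose(x.values, exp.features, atol=1e-12)

    def test_success_rule_threshold(self):
        exp = simulate_experiment(PerturbationSchedule(kind="probe"), seed=9)
        err = np.abs(exp.targets - exp.displayed)
        np.testing.assert_array_equal(exp.success, err < 0.02)

    def test_bitwise_determinism(self):
        a = simulate_experiment(PerturbationSchedule(kind="constant",
                                                     seed=2), seed=2)
        b = simulate_experiment(PerturbationSchedule(kind="constant",
                                                     seed=2), seed=2)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.heights, b.heights)
        np.testing.assert_array_equal(a.targets, b.targets)

    def test_linear_height_model_is_exact_readout(self):
        exp = simulate_experiment(PerturbationSchedule(kind="none"), seed=4,
                                  height_model="linear")
        w_lin = exp.feature_gain * exp.w_true
        diffs = (exp.features - exp.features[0]) @ w_lin
        np.testing.assert_allclose(exp.heights - exp.heights[0], diffs,
                                   atol=1e-10)


class TestWindows:
    def test_default_windows_avoid_perturbed_lead_in(self):
        p = make_schedule(PerturbationSchedule(kind="constant"))
        before, after = default_windows(p)
        assert before == (0, 5)
        assert after == (35, 45)

    def test_gradual_windows(self):
        p = make_schedule(PerturbationSchedule(kind="gradual"))
        before, after = default_windows(p)
        assert before == (0, 10)
        assert after == (20, 30)
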