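"""Model-error detection, random weighting and the strong-tracking correction."""

from functools import partial

import numpy as np
import pytest
from scipy import stats

from palpkf.hc_model import STATE_DIM, measurement_fn, state_transition
from palpkf.rwstukf import (
    DetectionConfig,
    InnovationWindow,
    InsufficientHistoryError,
    corrected_covariance,
    default_threshold,
    detect,
    draw_random_weights,
    mahalanobis,
    rw_innovation_cov,
    rwstukf_step,
    scaling_factor,
)
from palpkf.simulator import run_filter_on_scenario, scenario_preset
from palpkf.ukf import GaussianBelief, NoiseSpec, NumericalError


class TestMahalanobisDetection:
    @pytest.mark.parametrize(
        "z, S, expected",
        [
            ([0, 0], np.eye(2), 0.0),
            ([1, 0], np.eye(2), 1.0),
            ([1, 2], np.diag([1.0, 4.0]), 2.0),  # 1/1 + 4/4
        ],
    )
    def test_quadratic_form(self, z, S, expected):
        assert mahalanobis(np.array(z, dtype=float), S) == pytest.approx(expected)

    def test_singular_covariance_raises(self):
        with pytest.raises(NumericalError):
            mahalanobis(np.array([1.0, 0.0]), np.zeros((2, 2)))

    def test_boundary_is_not_a_detection(self):
        # theta == theta_T means "no model error"
        assert detect(9.21, 9.21) is False
        assert detect(0.0, 9.21) is False
        assert detect(9.21 + 1e-9, 9.21) is True

    def test_default_threshold_is_chi2_quantile(self):
        assert default_threshold() == pytest.approx(stats.chi2.ppf(0.99, 2))
        assert default_threshold(0.95) == pytest.approx(5.991464547107979)


class TestRandomWeights:
    def test_single_slot_is_deterministic(self, rng):
        assert np.array_equal(draw_random_weights(1, rng), [1.0])

    @pytest.mark.parametrize("m", [2, 4, 9])
    def test_weights_are_convex(self, m, rng):
        for _ in range(200):
            v = draw_random_weights(m, rng)
            assert v.shape == (m,)
            assert np.all(v >= 0)
            assert abs(v.sum() - 1.0) <= 1e-12

    def test_component_means_match_flat_dirichlet(self, rng):
        """Empirical component means converge to 1/M (unbiasedness of the
        random-weighted window estimate)."""
        m, draws = 4, 40000
        v = np.array([draw_random_weights(m, rng) for _ in range(draws)])
        se = np.sqrt(v.var(axis=0) / draws)
        assert np.all(np.abs(v.mean(axis=0) - 1.0 / m) < 3 * se + 1e-12)


class TestWindowCovariance:
    def test_single_innovation_outer_product(self):
        w = InnovationWindow(M=4)
        w.append(np.array([1.0, 0.0]))
        B0 = rw_innovation_cov(w, np.array([1.0]))
        assert np.allclose(B0, [[1, 0], [0, 0]])

    def test_equal_weights_reproduce_window_average(self, rng):
        w = InnovationWindow(M=5)
        zs = rng.normal(size=(5, 2))
        for z in zs:
            w.append(z)
        B0 = rw_innovation_cov(w, np.full(5, 0.2))
        avg = sum(np.outer(z, z) for z in zs) / 5
        assert np.allclose(B0, avg, atol=1e-14)

    def test_random_weighted_estimate_is_unbiased(self, rng):
        """Averaging the random-weighted covariance over many weight draws
        recovers the equal-weight estimate (flat Dirichlet has mean 1/M)."""
        w = InnovationWindow(M=4)
        zs = rng.normal(size=(4, 2)) * [1.0, 3.0]
        for z in zs:
            w.append(z)
        equal = rw_innovation_cov(w, np.full(4, 0.25))
        acc = np.zeros((2, 2))
        draws = 10000
        for _ in range(draws):
            acc += rw_innovation_cov(w, draw_random_weights(4, rng))
        mc = acc / draws
        assert np.trace(mc) == pytest.approx(np.trace(equal), rel=0.01)

    def test_eviction_keeps_most_recent(self):
        w = InnovationWindow(M=2)
        for k in range(4):
            w.append(np.array([float(k), 0.0]))
        assert np.allclose(w.as_array()[:, 0], [2.0, 3.0])

    def test_empty_window_raises(self):
        with pytest.raises(InsufficientHistoryError):
            rw_innovation_cov(InnovationWindow(M=3), np.array([]))


class TestScalingFactor:
    def test_consistent_filter_gives_unity(self):
        # tr(B0) == tr(R) + tr(HPH) -> gamma exactly 1
        assert scaling_factor(np.diag([2.0, 1.0]), np.eye(2), np.eye(2)) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        B0 = np.array([[4.0, 0.0], [0.0, 0.0]])
        R = np.diag([0.5, 0.5])
        HPH = np.diag([1.5, 0.5])
        assert scaling_factor(B0, R, HPH) == pytest.approx(1.5)

    def test_deflation_clamped_to_unity(self):
        assert scaling_factor(np.zeros((2, 2)), np.eye(2), np.eye(2)) == pytest.approx(1.0)

    def test_upper_bound(self):
        assert scaling_factor(1e6 * np.eye(2), np.eye(2), np.eye(2), gamma_max=5.0) == 5.0

    def test_degenerate_projection_raises(self):
        with pytest.raises(NumericalError):
            scaling_factor(np.eye(2), np.eye(2), np.zeros((2, 2)))

    def test_corrected_covariance_scales_trace(self):
        P = np.diag([1.0, 2.0, 3.0])
        assert np.allclose(corrected_covariance(P, 2.0), 2 * P)
        assert np.allclose(corrected_covariance(P, 1.0), P)
        assert np.trace(corrected_covariance(P, 3.5)) == pytest.approx(3.5 * np.trace(P))
        with pytest.raises(ValueError):
            corrected_covariance(P, 0.5)


class TestAdaptiveStep:
    def test_infinite_threshold_reproduces_plain_ukf(self):
        """With detection disabled the adaptive filter's output stream is
        bitwise identical to the standard UKF on the same measurements."""
        cfg = scenario_preset("init_error", n_steps=80, theta_T=np.inf)
        ukf = run_filter_on_scenario(cfg, "ukf", seed=7)
        rwst = run_filter_on_scenario(cfg, "rwstukf", seed=7)
        assert np.array_equal(ukf.estimates, rwst.estimates)
        assert not rwst.corrected.any()

    def test_forced_unit_gamma_reproduces_uncorrected_update(self, weights7, rng):
        """A detection whose window yields gamma = 1 redoes the measurement
        update without changing anything."""
        noise = NoiseSpec(np.diag([1e-8, 1e-8, 0.01, 1e-8, 1e-8, 1e-8, 1e-8]), 0.01 * np.eye(2))
        mean = np.array([0.5, 0.1, 2.5, 10.0, 1.0, 2.0, 1.05])
        belief = GaussianBelief(mean, 0.5 * np.eye(STATE_DIM))
        trans = partial(state_transition, dt=0.1)
        y_far = np.array([0.6, 8.0])  # large innovation -> certain detection
        cfg = DetectionConfig(M=4, theta_T=1e-6)

        # window of zero innovations -> B0 = 0 -> gamma clamps to 1
        win0 = InnovationWindow(M=4)
        win0.append(np.zeros(2))
        res_corr, diag, _ = rwstukf_step(
            belief, y_far, win0, cfg, noise, weights7, trans, measurement_fn, rng
        )
        assert diag.corrected
        assert diag.gamma == pytest.approx(1.0)

        win_none = InnovationWindow(M=4)  # empty window -> detection disabled
        res_plain, diag2, _ = rwstukf_step(
            belief, y_far, win_none, DetectionConfig(M=4), noise, weights7, trans, measurement_fn, rng
        )
        assert not diag2.corrected
        assert np.array_equal(res_corr.posterior.mean, res_plain.posterior.mean)
        assert np.array_equal(res_corr.posterior.cov, res_plain.posterior.cov)

    def test_detection_inflates_posterior_covariance(self, weights7, rng):
        noise = NoiseSpec(np.diag([1e-8, 1e-8, 0.01, 1e-8, 1e-8, 1e-8, 1e-8]), 0.01 * np.eye(2))
        mean = np.array([0.5, 0.1, 2.5, 10.0, 1.0, 2.0, 1.05])
        belief = GaussianBelief(mean, 0.1 * np.eye(STATE_DIM))
        trans = partial(state_transition, dt=0.1)
        y_far = np.array([0.6, 30.0])
        win = InnovationWindow(M=4)
        for _ in range(4):
            win.append(np.array([1.0, 10.0]))  # history of large innovations

        corr, diag, _ = rwstukf_step(
            belief, y_far, InnovationWindow(M=4, buffer=list(win.buffer)),
            DetectionConfig(M=4), noise, weights7, trans, measurement_fn, rng,
        )
        plain, _, _ = rwstukf_step(
            belief, y_far, InnovationWindow(M=4), DetectionConfig(M=4),
            noise, weights7, trans, measurement_fn, rng,
        )
        assert diag.corrected and diag.gamma > 1.0
        assert np.trace(corr.posterior.cov) > np.trace(plain.posterior.cov)

    def test_window_gets_the_final_innovation(self, weights7, rng):
        noise = NoiseSpec(1e-4 * np.eye(STATE_DIM), 0.01 * np.eye(2))
        belief = GaussianBelief(
            np.array([0.5, 0.1, 2.5, 10.0, 1.0, 2.0, 1.05]), 0.1 * np.eye(STATE_DIM)
        )
        win = InnovationWindow(M=3)
        res, _, win = rwstukf_step(
            belief, np.array([0.55, 2.6]), win, DetectionConfig(M=3),
            noise, weights7, partial(state_transition, dt=0.1), measurement_fn, rng,
        )
        assert len(win) == 1
        assert np.array_equal(win.as_array()[0], res.innovation)

    def test_detector_calibrated_under_matched_model(self):
        """With a correct model and matched noise levels the fraction of
        steps flagged at the chi-square 0.99 level stays below 3%."""
        cfg = scenario_preset("custom", n_steps=1000, seed=3)
        run = run_filter_on_scenario(cfg, "rwstukf", seed=3)
        theta = run.theta[np.isfinite(run.theta)]
        frac = np.mean(theta > default_threshold())
        assert frac <= 0.03

    def test_gamma_rises_during_injected_fault(self):
        """The scaling factor exceeds 1 inside the fault window for most
        Monte-Carlo repetitions of the transient-fault study."""
        cfg = scenario_preset("local_error")
        hits = 0
        n_runs = 6
        for seed in range(n_runs):
            run = run_filter_on_scenario(cfg, "rwstukf", seed=seed)
            lo, hi = cfg.local_error_window
            in_window = (run.steps >= lo) & (run.steps <= hi)
            if np.any(run.gamma[in_window] > 1.0):
                hits += 1
        assert hits > n_runs / 2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(M=0)
        with pytest.raises(ValueError):
            DetectionConfig(chi2_level=1.5)
        with pytest.raises(ValueError):
            DetectionConfig(theta_T=-1.0)
        with pytest.raises(ValueError):
            DetectionConfig(gamma_max=0.5)
        with pytest.raises(ValueError):
            InnovationWindow(M=0)
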