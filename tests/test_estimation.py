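"""Kalman and FSP filter correctness against independent Bayes oracles."""

import math

import numpy as np
import pytest
from scipy.stats import norm, poisson

from reactoscope.cells import GeneExpressionParams, LightProfile, simulate_ssa
from reactoscope.estimation import (FspState, KalmanState, buffer_length,
                                    default_truncation, fit_deterministic,
                                    fsp_init, fsp_propagate, fsp_update,
                                    kalman_step, transition_matrix)
from reactoscope.scenarios import (characterization_profiles,
                                   simulate_characterization_data)


class DenseGridBayesFilter:
    """Brute-force Bayes filter on a dense state grid.

    Independent oracle for the Kalman recursion: the same linear-Gaussian
    model, but propagated by numerically integrating the Chapman-Kolmogorov
    equation over a fine grid instead of closed-form Gaussian algebra.
    """

    def __init__(self, params, step_min, q, grid_max, n_points=4096):
        self.params = params
        self.step = step_min
        self.q = q
        self.x = np.linspace(0.0, grid_max, n_points)
        self.p = None

    def init_gaussian(self, mean, var):
        self.p = norm.pdf(self.x, mean, math.sqrt(var))
        self.p /= self.p.sum()

    def predict(self, u):
        par = self.params
        decay = math.exp(-par.gamma * self.step)
        drift = (par.b0 + par.k * u) / par.gamma * (1.0 - decay)
        mu = self.x * decay + drift  # deterministic map of each grid point
        sd = math.sqrt(self.q)
        trans = norm.pdf(self.x[:, None], mu[None, :], sd)
        p_new = trans @ self.p
        self.p = p_new / p_new.sum()

    def update(self, y):
        lik = norm.pdf(y, self.params.alpha * self.x, self.params.sigma_meas)
        self.p = self.p * lik
        self.p /= self.p.sum()

    def mean(self):
        return float(np.dot(self.x, self.p))


class TestKalman:
    def test_tight_measurement_dominates(self):
        p = GeneExpressionParams(k=1.0, b0=0.1, gamma=0.01, tau=0.0,
                                 alpha=1.0, sigma_meas=1e-6)
        st = KalmanState(mean=10.0, variance=100.0)
        out = kalman_step(st, False, 57.0, p, q=0.0)
        assert out.mean == pytest.approx(57.0, abs=1e-3)

    def test_predict_only_equals_deterministic_model(self):
        p = GeneExpressionParams(k=3.0, b0=0.2, gamma=0.02, tau=0.0)
        st = KalmanState(mean=40.0, variance=4.0)
        out = kalman_step(st, True, None, p, step_min=6.0, q=0.0)
        decay = math.exp(-p.gamma * 6.0)
        expected = 40.0 * decay + (p.b0 + p.k) / p.gamma * (1.0 - decay)
        assert out.mean == pytest.approx(expected, rel=1e-12)
        assert out.variance == pytest.approx(4.0 * decay ** 2, rel=1e-12)

    def test_variance_never_increases_at_update(self):
        p = GeneExpressionParams(sigma_meas=30.0, alpha=1.0)
        st = KalmanState(mean=100.0, variance=50.0)
        out = kalman_step(st, False, 120.0, p, q=10.0)
        predicted_var = 50.0 * math.exp(-2 * p.gamma * 6.0) + 10.0
        assert out.variance <= predicted_var

    def test_measurement_with_bad_sigma_rejected(self):
        p = GeneExpressionParams(sigma_meas=0.0)
        with pytest.raises(ValueError):
            kalman_step(KalmanState(1.0, 1.0), False, 5.0, p)

    def test_buffer_shifts_with_applied_light(self):
        p = GeneExpressionParams(tau=18.0)
        st = KalmanState(0.0, 0.0, input_buffer=(1.0, 0.0, 0.0))
        out = kalman_step(st, True, None, p, q=0.0)
        assert out.input_buffer == (0.0, 0.0, 1.0)

    def test_matches_dense_grid_bayes_filter(self, rng):
        # 20-step run with measurements: posterior means within 1%
        p = GeneExpressionParams(k=5.0, b0=0.5, gamma=0.02, tau=12.0,
                                 alpha=1.0, sigma_meas=8.0)
        q = 4.0
        D = buffer_length(p.tau, 6.0)
        kal = KalmanState(mean=100.0, variance=25.0, input_buffer=(0.0,) * D)
        oracle = DenseGridBayesFilter(p, 6.0, q, grid_max=400.0)
        oracle.init_gaussian(100.0, 25.0)
        lights = rng.random(20) < 0.5
        truth = 100.0
        for j in range(20):
            u = kal.input_buffer[0]
            y = truth + rng.normal(0, p.sigma_meas)
            oracle.predict(float(u))
            oracle.update(y)
            kal = kalman_step(kal, bool(lights[j]), float(y), p, q=q)
            assert kal.mean == pytest.approx(oracle.mean(), rel=0.01)


class TestFspPropagate:
    def test_zero_dt_is_identity(self, expr_params):
        st = fsp_init(50, 10, expr_params.tau, 6.0)
        out = fsp_propagate(st, True, 0.0, expr_params)
        assert np.array_equal(out.p, st.p)
        assert out.leaked == st.leaked

    def test_zero_rates_leave_state_unchanged(self):
        p = GeneExpressionParams(k=0.0, b0=0.0, gamma=1e-12, tau=0.0)
        st = fsp_init(30, 5, 0.0, 6.0)
        out = fsp_propagate(st, False, 6.0, p)
        assert out.p[5] == pytest.approx(1.0, abs=1e-9)
        assert out.leaked == pytest.approx(0.0, abs=1e-12)

    def test_probability_conservation(self):
        p = GeneExpressionParams(k=2.0, b0=0.1, gamma=0.02, tau=0.0)
        st = fsp_init(default_truncation(p), 0, 0.0, 6.0)
        for _ in range(50):
            st = fsp_propagate(st, True, 6.0, p)
            assert st.p.sum() + st.leaked == pytest.approx(1.0, abs=1e-9)

    def test_leaked_mass_monotone_between_updates(self):
        p = GeneExpressionParams(k=2.0, b0=0.1, gamma=0.05, tau=0.0)
        st = fsp_init(30, 0, 0.0, 6.0)  # deliberately tight truncation
        leaks = []
        with pytest.warns(UserWarning):
            for _ in range(30):
                st = fsp_propagate(st, True, 6.0, p)
                leaks.append(st.leaked)
        assert all(b >= a for a, b in zip(leaks, leaks[1:]))
        assert leaks[-1] > 0

    def test_stationary_matches_poisson(self):
        # long constant-input propagation: TV vs analytic Poisson < 1e-3
        p = GeneExpressionParams(k=0.0, b0=1.0, gamma=0.05, tau=0.0)
        mean = p.b0 / p.gamma  # 20
        N = int(8 * mean)
        st = fsp_init(N, 0, 0.0, 6.0)
        for _ in range(60):  # 360 min >> 1/gamma
            st = fsp_propagate(st, False, 6.0, p)
        ana = poisson.pmf(np.arange(N + 1), mean)
        tv = 0.5 * np.abs(st.p / st.p.sum() - ana / ana.sum()).sum()
        assert tv < 1e-3


class TestFspUpdate:
    def test_flat_likelihood_keeps_prior(self):
        p = GeneExpressionParams(alpha=1.0, sigma_meas=1e9)
        prior = np.exp(-0.5 * ((np.arange(61) - 30) / 5.0) ** 2)
        st = FspState(prior / prior.sum(), leaked=0.1)
        out = fsp_update(st, 45.0, p)
        assert np.allclose(out.p, prior / prior.sum(), atol=1e-6)
        assert out.leaked == 0.0  # reset after renormalization

    def test_sharp_likelihood_concentrates(self):
        p = GeneExpressionParams(alpha=2.0, sigma_meas=0.01)
        st = FspState(np.full(101, 1 / 101))
        out = fsp_update(st, 2.0 * 42, p)
        assert out.p.argmax() == 42
        assert out.p[42] > 0.999

    def test_incompatible_measurement_falls_back_to_prior(self):
        p = GeneExpressionParams(alpha=1.0, sigma_meas=0.5)
        prior = np.zeros(51)
        prior[:5] = 0.2
        st = FspState(prior)
        out = fsp_update(st, 1e6, p)
        assert np.allclose(out.p, prior / prior.sum())

    def test_ten_updates_match_direct_bayes_recursion(self, rng):
        # oracle: explicit prior*likelihood/normalize recursion with the
        # same transition matrices, written independently
        p = GeneExpressionParams(k=1.0, b0=0.2, gamma=0.03, tau=0.0,
                                 alpha=3.0, sigma_meas=10.0)
        N = 80
        T = transition_matrix(N, p.b0 + p.k, p.gamma, 6.0)
        st = fsp_init(N, 20, 0.0, 6.0)
        q = np.zeros(N + 1)
        q[20] = 1.0
        ns = np.arange(N + 1)
        for _ in range(10):
            y = float(rng.uniform(40, 140))
            st = fsp_propagate(st, True, 6.0, p)
            st = fsp_update(st, y, p)
            q = T @ q
            lik = np.exp(-0.5 * ((y - p.alpha * ns) / p.sigma_meas) ** 2)
            q = q * lik
            q = q / q.sum()
            assert np.allclose(st.p, q, atol=1e-10)


class TestFspKalmanAgreement:
    def test_posterior_means_agree_at_high_counts(self, rng):
        # FSP -> Gaussian regime: relative difference < 5% at mean ~250
        p = GeneExpressionParams(k=0.0, b0=5.0, gamma=0.02, tau=0.0,
                                 alpha=1.0, sigma_meas=20.0)
        mean = p.b0 / p.gamma  # 250
        N = 600
        fsp = FspState(poisson.pmf(np.arange(N + 1), mean))
        kal = KalmanState(mean=mean, variance=mean)
        for _ in range(8):
            y = float(mean + rng.normal(0, p.sigma_meas))
            fsp = fsp_propagate(fsp, False, 6.0, p)
            fsp = fsp_update(fsp, y, p)
            kal = kalman_step(kal, False, y, p)
            assert abs(fsp.mean() - kal.mean) / kal.mean < 0.05


class TestFilterConsistency:
    def test_credible_interval_coverage_on_ssa_truth(self, rng):
        # 90% central credible interval covers the true SSA count
        # ~90% +/- 5% of measurement times over 200 cells
        p = GeneExpressionParams(k=1.0, b0=0.2, gamma=0.02, tau=12.0,
                                 alpha=3.0, sigma_meas=15.0)
        N = 240
        D = buffer_length(p.tau, 6.0)
        steps = 15
        hits = total = 0
        for _ in range(200):
            pulses = tuple(bool(b) for b in rng.random(steps + D) < 0.5)
            light = LightProfile(pulses, step_min=6.0)
            times, counts = simulate_ssa(
                p, light, (steps + 1) * 6.0, rng, n0=20,
                sample_times=np.arange(steps + 1) * 6.0)
            st = fsp_init(N, 20, p.tau, 6.0)
            for j in range(1, steps + 1):
                st = fsp_propagate(st, pulses[j - 1], 6.0, p)
                y = p.alpha * counts[j] + rng.normal(0, p.sigma_meas)
                st = fsp_update(st, float(y), p)
                lo, hi = st.credible_interval(0.9)
                hits += lo <= counts[j] <= hi
                total += 1
        assert abs(hits / total - 0.90) < 0.05


class TestFitDeterministic:
    def test_noiseless_self_consistency(self):
        true = GeneExpressionParams(k=15.0, b0=0.5, gamma=0.01, tau=36.0,
                                    alpha=1.0)
        times, noisy, lights = simulate_characterization_data(
            true, 50, np.random.default_rng(0), noise_frac=0.0)
        fit = fit_deterministic(times, noisy, lights)
        assert fit.params.k == pytest.approx(true.k, rel=0.01)
        assert fit.params.gamma == pytest.approx(true.gamma, rel=0.01)
        # delay identifiable only to the 6-min sampling interval
        assert abs(fit.params.tau - true.tau) <= 3.0

    def test_single_profile_sets_identifiability_flag(self):
        true = GeneExpressionParams(k=10.0, b0=0.1, gamma=0.02, tau=0.0)
        lights = [characterization_profiles(20)[0]] * 2
        from reactoscope.cells import simulate_deterministic

        _, traj = simulate_deterministic(true, lights[0], 120.0, dt_min=6.0)
        times = np.arange(0, 121, 6.0)
        fit = fit_deterministic(times, [traj, traj], lights,
                                tau_grid=np.array([0.0]))
        assert fit.identifiability_warning
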