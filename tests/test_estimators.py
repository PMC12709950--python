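import numpy as np
import pytest

import germisample as gs
from germisample.estimators import (
    ChainStuckError,
    EstimatorConfig,
    ExtendedKalmanFilter,
    SIRParticleFilter,
    _gompertz_mat,
)

from _oracles import (
    A_ONLY,
    A_ONLY_T,
    a_only_data,
    a_only_priors,
    conjugate_posterior_a,
    conjugate_predictive,
    regressor,
)

T_QUERY = 48.0


@pytest.fixture(scope="module")
def a_priors(timeline):
    p = A_ONLY
    return a_only_priors(
        p["mu0"], p["tau0"], p["b"], p["c"], p["sigma"], timeline, n_particles=4000
    )


@pytest.fixture(scope="module")
def a_data():
    return a_only_data()


def _gaussian_oracle(kept_t, kept_y, flat=False):
    p = A_ONLY
    mu0, tau0 = (None, None) if flat else (p["mu0"], p["tau0"])
    pm, pv = conjugate_posterior_a(
        kept_t, kept_y, p["b"], p["c"], p["sigma"], mu0=mu0, tau0=tau0
    )
    mean, std = conjugate_predictive(T_QUERY, p["b"], p["c"], p["sigma"], pm, pv)
    return pm, pv, mean, std


class TestImportanceSampling:
    def test_no_data_gives_uniform_weights(self, training_priors):
        pred, est = gs.is_predict([], [], 40.0, training_priors)
        n = len(training_priors.param_samples)
        assert est.diagnostics["ess"] == pytest.approx(n)
        thetas = np.array([p.as_array() for p in training_priors.param_samples])
        prior_pred = _gompertz_mat(np.array([40.0]), thetas)[:, 0].mean()
        assert pred.mean == pytest.approx(prior_pred)

    def test_matches_conjugate_gaussian(self, a_priors, a_data):
        kt, ky = a_data
        pred, est = gs.is_predict(kt, ky, T_QUERY, a_priors)
        _, pv, mean, std = _gaussian_oracle(kt, ky)
        ess = est.diagnostics["ess"]
        se_mean = regressor(T_QUERY, A_ONLY["b"], A_ONLY["c"]) * np.sqrt(pv / ess)
        assert abs(pred.mean - mean) < 3 * se_mean
        assert abs(pred.std - std) < 3 * std / np.sqrt(2 * ess)

    def test_noise_floor(self, training_priors):
        pred, _ = gs.is_predict([], [], 60.0, training_priors)
        assert pred.std >= training_priors.sigma_eta_mean


class TestMetropolis:
    def test_prior_only_chain_samples_uniform(self, training_priors):
        az = pytest.importorskip("arviz")
        from germisample.estimators import _mcmc_bounds, _rw_metropolis

        cfg = EstimatorConfig(method="MCMC", n_samples=40_000, rng_seed=1)
        pred, est = gs.mcmc_predict([], [], 40.0, training_priors, cfg)
        lo, hi = _mcmc_bounds(training_priors)
        mid = 0.5 * (lo + hi)
        sd = (hi - lo) / np.sqrt(12.0)
        post = np.append(est.theta_hat.as_array(), est.sigma_eta_hat)
        # replay the chain to get autocorrelation-adjusted standard errors
        init = np.clip(
            np.append(training_priors.param_mean, training_priors.sigma_eta_mean),
            lo, hi,
        )
        scales = cfg.proposal_scale_fraction * (hi - lo)
        empty = np.array([])
        chain, _ = _rw_metropolis(empty, empty, lo, hi, init, scales, 40_000, 1)
        draws = chain[8000:]
        for k in range(4):
            ess = float(az.ess(draws[None, :, k]))
            assert abs(post[k] - mid[k]) < 3 * sd[k] / np.sqrt(ess)

    def test_matches_flat_prior_gaussian_posterior(self, a_priors, a_data):
        az = pytest.importorskip("arviz")
        from germisample.estimators import _mcmc_bounds, _rw_metropolis

        kt, ky = a_data
        cfg = EstimatorConfig(method="MCMC", n_samples=30_000, rng_seed=3)
        pred, est = gs.mcmc_predict(kt, ky, T_QUERY, a_priors, cfg)
        pm, pv, mean, std = _gaussian_oracle(kt, ky, flat=True)
        # reproduce the chain to estimate its autocorrelation-adjusted SE
        lo, hi = _mcmc_bounds(a_priors)
        init = np.append(a_priors.param_mean, a_priors.sigma_eta_mean)
        scales = cfg.proposal_scale_fraction * (hi - lo)
        chain, _ = _rw_metropolis(kt, ky, lo, hi, init, scales, 30_000, 3)
        a_draws = chain[6000:, 0]
        ess = float(az.ess(a_draws[None, :]))
        se_a = np.sqrt(pv / ess)
        assert abs(est.theta_hat.a - pm) < 3 * se_a
        mq = regressor(T_QUERY, A_ONLY["b"], A_ONLY["c"])
        assert abs(pred.mean - mean) < 3 * mq * se_a
        assert abs(pred.std - std) < 3 * std / np.sqrt(2 * ess)

    def test_seed_determinism(self, training_priors, a_data):
        kt, ky = a_data
        cfg = EstimatorConfig(method="MCMC", n_samples=2000, rng_seed=7)
        p1, e1 = gs.mcmc_predict(kt, ky, T_QUERY, training_priors, cfg)
        p2, e2 = gs.mcmc_predict(kt, ky, T_QUERY, training_priors, cfg)
        assert p1 == p2 and e1.theta_hat == e2.theta_hat
        p3, _ = gs.mcmc_predict(
            kt, ky, T_QUERY, training_priors,
            EstimatorConfig(method="MCMC", n_samples=2000, rng_seed=8),
        )
        assert p3 != p1

    def test_default_chain_length(self):
        assert EstimatorConfig(method="MCMC").resolved_samples() == 10_000


class TestGaussianProcess:
    def test_hand_computed_three_point_conditioning(self):
        # tiny grid, hand-built covariance, textbook partitioned formula
        tl = gs.Timeline([0.0, 2.0, 4.0])
        C = np.array([[4.0, 2.0, 1.0], [2.0, 5.0, 2.0], [1.0, 2.0, 6.0]])
        mu = np.array([10.0, 20.0, 30.0])
        sigma = 1.5
        priors = a_only_priors(95, 3, 8, 0.08, sigma, tl, n_particles=10)
        priors.curve_mean = mu
        priors.curve_cov = C
        y_obs = np.array([11.0, 19.0])
        pred, _ = gs.gp_predict([0.0, 4.0], [y_obs[0], y_obs[1]], 2.0, priors,
                                estimate_theta=False)
        S = C + sigma**2 * np.eye(3)
        kk = S[np.ix_([0, 2], [0, 2])]
        qk = S[1, [0, 2]]
        inv = np.linalg.inv(kk)
        mean = mu[1] + qk @ inv @ (y_obs - mu[[0, 2]])
        var = S[1, 1] - qk @ inv @ qk
        assert pred.mean == pytest.approx(mean, abs=1e-10)
        assert pred.std == pytest.approx(np.sqrt(var), abs=1e-10)

    def test_no_data_returns_prior(self, training_priors):
        pred, _ = gs.gp_predict([], [], 40.0, training_priors, estimate_theta=False)
        i = training_priors.timeline.index_of(40.0)
        assert pred.mean == pytest.approx(training_priors.curve_mean[i])
        expect = np.sqrt(
            training_priors.curve_cov[i, i] + training_priors.sigma_eta_mean**2
        )
        assert pred.std == pytest.approx(expect)

    def test_conditioning_on_queried_coordinate(self, training_priors, noisy_curve):
        y16 = noisy_curve.values[8]
        prior_mean = training_priors.curve_mean[8]
        pred, _ = gs.gp_predict([0.0, 8.0, 16.0],
                                [noisy_curve.values[0], noisy_curve.values[4], y16],
                                16.0, training_priors, estimate_theta=False)
        assert pred.std <= training_priors.sigma_eta_mean * (1 + 1e-9)
        assert abs(pred.mean - y16) < abs(prior_mean - y16)

    def test_variance_monotone_in_kept_points(self, training_priors, noisy_curve):
        times = [0.0, 8.0, 16.0, 24.0, 32.0]
        idx = [training_priors.timeline.index_of(t) for t in times]
        prev = np.inf
        for k in range(len(times) + 1):
            pred, _ = gs.gp_predict(
                times[:k], noisy_curve.values[idx][:k], 60.0, training_priors,
                estimate_theta=False,
            )
            assert pred.std <= prev + 1e-12
            prev = pred.std

    def test_matches_conjugate_gaussian_exactly(self, a_priors, a_data):
        kt, ky = a_data
        pred, _ = gs.gp_predict(kt, ky, T_QUERY, a_priors, estimate_theta=False)
        _, _, mean, std = _gaussian_oracle(kt, ky)
        assert pred.mean == pytest.approx(mean, abs=1e-8)
        assert pred.std == pytest.approx(std, abs=1e-8)


class TestExtendedKalman:
    def test_matches_conjugate_gaussian_exactly(self, a_priors, a_data):
        kt, ky = a_data
        preds, est = gs.ekf_run(list(zip(kt, ky)), [T_QUERY], a_priors)
        pm, pv, mean, std = _gaussian_oracle(kt, ky)
        assert preds[0].mean == pytest.approx(mean, abs=1e-8)
        assert preds[0].std == pytest.approx(std, abs=1e-8)
        assert est.theta_hat.a == pytest.approx(pm, abs=1e-8)

    def test_prior_propagation_without_data(self, training_priors):
        preds, _ = gs.ekf_run([], [40.0, 80.0], training_priors)
        for t, pred in zip([40.0, 80.0], preds):
            H = gs.gompertz_jacobian(
                t, gs.GompertzParams.from_array(training_priors.param_mean)
            )
            var = H @ training_priors.param_cov @ H + training_priors.sigma_eta_mean**2
            assert pred.std == pytest.approx(np.sqrt(var), rel=1e-10)

    def test_information_never_decreases(self, training_priors, noisy_curve):
        f = ExtendedKalmanFilter(training_priors)
        tr = np.trace(f.P)
        for _ in range(3):
            f.assimilate(40.0, noisy_curve.values[20])
            assert np.trace(f.P) < tr
            tr = np.trace(f.P)


class TestSIRParticleFilter:
    def test_prior_predictive_matches_big_n_monte_carlo(self, training_priors):
        cfg = EstimatorConfig(method="SIR", rng_seed=2)
        f = SIRParticleFilter(training_priors, cfg)
        pred = f.predict(40.0)
        # fresh large-sample estimate of the same uniform prior predictive
        rng = np.random.default_rng(123)
        lo = np.append(training_priors.param_bounds[:, 0],
                       training_priors.sigma_eta_bounds[0])
        hi = np.append(training_priors.param_bounds[:, 1],
                       training_priors.sigma_eta_bounds[1])
        big = rng.uniform(lo, hi, size=(1_000_000, 4))
        g = big[:, 0] * np.exp(-big[:, 1] * np.exp(-big[:, 2] * 40.0))
        var = g.var() + np.mean(big[:, 3] ** 2)
        se = g.std() / np.sqrt(2000)
        assert abs(pred.mean - g.mean()) < 4 * se
        assert abs(pred.std - np.sqrt(var)) < 4 * se

    def test_matches_flat_prior_gaussian_posterior(self, a_priors, a_data):
        kt, ky = a_data
        cfg = EstimatorConfig(
            method="SIR", n_samples=20_000, roughening_scale=0.0,
            resample_threshold_fraction=0.0, rng_seed=4,
        )
        preds, est = gs.sir_run(list(zip(kt, ky)), [T_QUERY], a_priors, cfg)
        pm, pv, mean, std = _gaussian_oracle(kt, ky, flat=True)
        ess = est.diagnostics["ess"]
        mq = regressor(T_QUERY, A_ONLY["b"], A_ONLY["c"])
        se = mq * np.sqrt(pv / ess)
        assert abs(preds[0].mean - mean) < 3 * se
        assert abs(preds[0].std - std) < 3 * std / np.sqrt(2 * ess)
        assert abs(est.theta_hat.a - pm) < 3 * np.sqrt(pv / ess)

    def test_weights_normalised_after_updates(self, training_priors, noisy_curve):
        f = SIRParticleFilter(training_priors, EstimatorConfig(method="SIR", rng_seed=0))
        for i in (0, 4, 8, 12):
            f.assimilate(noisy_curve.timeline.times[i], noisy_curve.values[i])
            assert f._weights().sum() == pytest.approx(1.0, abs=1e-12)

    def test_resampling_triggered_and_clipped(self, training_priors, noisy_curve):
        f = SIRParticleFilter(training_priors, EstimatorConfig(method="SIR", rng_seed=0))
        for i in range(0, 40, 4):
            f.assimilate(noisy_curve.timeline.times[i], noisy_curve.values[i])
        assert f.n_resample > 0
        assert np.all(f.particles >= f.lo - 1e-12)
        assert np.all(f.particles <= f.hi + 1e-12)

    def test_default_particle_count(self):
        assert EstimatorConfig(method="SIR").resolved_samples() == 2000
        assert EstimatorConfig(method="IS").resolved_samples() == 99

    def test_seed_determinism(self, training_priors, noisy_curve):
        stream = [(noisy_curve.timeline.times[i], noisy_curve.values[i]) for i in (0, 4, 8)]
        cfg = EstimatorConfig(method="SIR", rng_seed=5)
        p1, e1 = gs.sir_run(stream, [40.0], training_priors, cfg)
        p2, e2 = gs.sir_run(stream, [40.0], training_priors, cfg)
        assert p1 == p2 and e1.theta_hat == e2.theta_hat
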