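"""GP branch-point model: kernel, covariance validity, fitting, recovery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from chronosom.perturbation_time import (
    GPHyperParams,
    TimeCoursePair,
    analyze_spot,
    branch_log_likelihood,
    build_joint_covariance,
    fit_deviation,
    fit_hyperparameters,
    perturbation_posterior,
    rbf_kernel,
    shared_log_likelihood,
)
from tests.conftest import make_time_course

P = GPHyperParams(signal_var=1.0, lengthscale=10.0, noise_var=0.05)


class TestRbfKernel:
    def test_diagonal_is_signal_variance(self):
        assert rbf_kernel(3.0, 3.0, P) == pytest.approx(1.0)

    def test_hand_value(self):
        # sigma_f^2=1, l=10, |t-t'|=10 -> exp(-0.5)
        assert rbf_kernel(0.0, 10.0, P) == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_symmetry(self, rng):
        t = rng.uniform(0, 90, 12)
        K = rbf_kernel(t, t, P)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), P.signal_var)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GPHyperParams(-1.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            GPHyperParams(1.0, 10.0, 0.1, deviation_var=0.0)


class TestJointCovariance:
    def test_branch_beyond_data_equals_shared_model(self):
        pair = make_time_course(30.0, 0.9, seed=0)
        tau = pair.ages.max() + 1.0
        C = build_joint_covariance(pair, tau, P)
        t = pair.ages
        shared = rbf_kernel(t, t, P) + P.noise_var * np.eye(len(t))
        assert np.allclose(C, shared)

    def test_disease_variance_continuous_at_tau(self):
        """The pinned term vanishes at s = t = tau by construction."""
        tau = 40.0
        pair = TimeCoursePair(
            t_ctrl=np.array([0.0, 20.0, 80.0]),
            y_ctrl=np.zeros(3),
            t_dis=np.array([tau, tau + 1e-9, 60.0]),
            y_dis=np.zeros(3),
        )
        C_branch = build_joint_covariance(pair, tau, P, include_noise=False)
        C_shared = build_joint_covariance(pair, pair.ages.max() + 1, P, include_noise=False)
        # the observation exactly AT tau gains no deviation variance
        assert C_branch[3, 3] == pytest.approx(C_shared[3, 3], abs=1e-12)
        # just after tau the added variance is ~0 (continuity)
        assert C_branch[4, 4] - C_shared[4, 4] == pytest.approx(0.0, abs=1e-12)

    def test_psd_over_random_draws(self, rng):
        """Minimum eigenvalue >= -1e-8 before jitter for 100 random
        (tau, hyperparameters, age-set) draws."""
        worst = 0.0
        for _ in range(100):
            n_c, n_d = rng.integers(3, 15, 2)
            pair = TimeCoursePair(
                t_ctrl=np.sort(rng.uniform(0, 100, n_c)),
                y_ctrl=rng.normal(size=n_c),
                t_dis=np.sort(rng.uniform(0, 100, n_d)),
                y_dis=rng.normal(size=n_d),
            )
            params = GPHyperParams(
                signal_var=float(10 ** rng.uniform(-2, 2)),
                lengthscale=float(rng.uniform(1, 100)),
                noise_var=float(10 ** rng.uniform(-4, 0)),
                deviation_var=float(10 ** rng.uniform(-2, 2)),
                deviation_lengthscale=float(rng.uniform(1, 15)),
            )
            tau = float(rng.uniform(-10, 110))
            C = build_joint_covariance(pair, tau, params, include_noise=False)
            mineig = float(np.linalg.eigvalsh(C).min())
            worst = min(worst, mineig / max(params.signal_var, params.dev_var))
        assert worst >= -1e-8

    def test_infinite_tau_rejected(self):
        pair = make_time_course(30.0, 0.9, seed=1)
        with pytest.raises(ValueError, match="finite"):
            build_joint_covariance(pair, np.inf, P)


class TestLogLikelihoodOracle:
    def test_matches_dense_mvn_logpdf_on_grid(self):
        """The optimized Cholesky log-likelihood equals scipy's dense
        multivariate-normal log-density at every grid tau within 1e-6."""
        pair = make_time_course(30.0, 0.9, seed=2, n_ctrl=25, n_dis=15)
        params = GPHyperParams(0.8, 20.0, 0.09, deviation_var=0.5,
                               deviation_lengthscale=8.0)
        grid = np.linspace(pair.t_ctrl.min(), pair.t_ctrl.max(), 25)
        for tau in grid:
            ours = branch_log_likelihood(pair, tau, params)
            C = build_joint_covariance(pair, tau, params)
            oracle = multivariate_normal.logpdf(
                pair.values, mean=np.zeros(len(pair.values)), cov=C
            )
            assert ours == pytest.approx(oracle, abs=1e-6)


class TestFitHyperparameters:
    def test_lengthscale_recovery_from_known_gp(self):
        """Data from a known GP (sigma_f^2=1, l=20, sigma_n^2=0.01, n=120):
        fitted lengthscale within a factor of 2 in >=80% of replicates."""
        true = GPHyperParams(1.0, 20.0, 0.01)
        ok = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            t = np.sort(rng.uniform(0, 100, 120))
            K = rbf_kernel(t, t, true) + true.noise_var * np.eye(120)
            y = rng.multivariate_normal(np.zeros(120), K)
            pair = TimeCoursePair(t[:70], y[:70], t[70:], y[70:])
            fit = fit_hyperparameters(pair, seed=seed)
            ok += 10.0 <= fit.lengthscale <= 40.0
        assert ok >= 0.8 * n_rep

    def test_pure_noise_gives_small_signal_ratio(self):
        rng = np.random.default_rng(0)
        pair = TimeCoursePair(
            np.sort(rng.uniform(0, 80, 40)), rng.normal(0, 1, 40),
            np.sort(rng.uniform(18, 80, 30)), rng.normal(0, 1, 30),
        )
        fit = fit_hyperparameters(pair, seed=0)
        assert fit.signal_var / fit.noise_var < 0.5

    def test_scale_equivariance(self):
        pair = make_time_course(30.0, 0.9, seed=3)
        fit1 = fit_hyperparameters(pair, seed=1)
        doubled = TimeCoursePair(pair.t_ctrl, 2 * pair.y_ctrl, pair.t_dis, 2 * pair.y_dis)
        fit2 = fit_hyperparameters(doubled, seed=1)
        assert fit2.signal_var == pytest.approx(4 * fit1.signal_var, rel=0.05)
        assert fit2.noise_var == pytest.approx(4 * fit1.noise_var, rel=0.05)
        assert fit2.lengthscale == pytest.approx(fit1.lengthscale, rel=0.05)

    def test_constant_data_rejected(self):
        pair = TimeCoursePair(
            np.array([1.0, 2, 3]), np.ones(3), np.array([20.0, 30, 40]), np.ones(3)
        )
        with pytest.raises(ValueError, match="constant"):
            fit_hyperparameters(pair)


class TestPerturbationPosterior:
    def test_posterior_normalization_and_map_on_grid(self):
        pair = make_time_course(30.0, 0.9, seed=4)
        params = fit_hyperparameters(pair, seed=4)
        params = fit_deviation(pair, params)
        res = perturbation_posterior(pair, params)
        assert res.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.map_tau in res.tau_grid
        assert res.map_tau == res.tau_grid[np.argmax(res.posterior)]
        assert res.likelihood_ratio >= 0.0

    def test_nesting_shared_limit(self):
        """At tau beyond all data the branch log-likelihood equals the shared
        model's within 1e-9; the best tau is at least as good."""
        pair = make_time_course(30.0, 0.9, seed=5)
        params = fit_hyperparameters(pair, seed=5)
        ll_shared = shared_log_likelihood(pair, params)
        ll_far = branch_log_likelihood(pair, pair.ages.max() + 5.0, params)
        assert ll_far == pytest.approx(ll_shared, abs=1e-9)
        grid = np.append(
            np.linspace(pair.t_ctrl.min(), pair.t_ctrl.max(), 30),
            pair.ages.max() + 5.0,
        )
        res = perturbation_posterior(pair, params, tau_grid=grid)
        assert res.log_likelihood.max() >= ll_shared - 1e-9

    def test_identical_arms_flat_posterior_lr_one(self):
        """Disease arm copied point-for-point from control ages: LR <= 1+1e-6
        and the posterior is close to flat."""
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 85, 40))
        y = 0.5 - 1.0 / (1.0 + np.exp(-(t - 40) / 12.0)) + rng.normal(0, 0.2, 40)
        pair = TimeCoursePair(t, y, t, y)
        res = analyze_spot(pair, seed=6)
        assert res.likelihood_ratio <= 1.0 + 1e-6
        ratio = res.posterior.max() / res.posterior.min()
        assert ratio < 10.0

    def test_recovery_of_planted_tau30(self):
        """Planted tau=30, amplitude 3x noise: MAP within +-7.5 y in >=80% of
        seeded replicates, LR > 1 in all."""
        hits, lrs = 0, []
        n_rep = 10
        for seed in range(n_rep):
            pair = make_time_course(30.0, 0.9, seed=seed)
            res = analyze_spot(pair, seed=seed)
            hits += abs(res.map_tau - 30.0) <= 7.5
            lrs.append(res.likelihood_ratio)
        assert hits >= 0.8 * n_rep
        assert all(lr > 1.0 for lr in lrs)

    def test_recovery_error_decreases_with_amplitude(self):
        """Median |MAP - tau| decreases from amplitude 2x to 5x noise sd."""
        med = {}
        for mult in (2.0, 5.0):
            errs = []
            for seed in range(6):
                for tau in (30.0, 60.0):
                    pair = make_time_course(tau, mult * 0.3, seed=seed)
                    res = analyze_spot(pair, seed=seed)
                    errs.append(abs(res.map_tau - tau))
            med[mult] = np.median(errs)
        assert med[5.0] <= med[2.0]

    def test_early_tau_identifiability_caveat(self):
        """Planted tau=5 with divergence persisting past age 18: MAP lands
        within +-10 y (it cannot resolve ages before the first disease
        sample, so it reports an early age).  A divergence that vanishes by
        age 18 yields a posterior with no sharp peak below 18."""
        hits = 0
        for seed in range(6):
            pair = make_time_course(5.0, 0.9, seed=seed)
            res = analyze_spot(pair, seed=seed)
            hits += abs(res.map_tau - 5.0) <= 10.0
        assert hits >= 4
        # transient divergence: ramp up then back to zero before age 18
        rng = np.random.default_rng(1)
        t_c = np.sort(rng.uniform(0, 85, 60))
        t_d = np.sort(rng.uniform(18, 85, 40))
        bump = lambda a: 0.9 * np.exp(-((a - 10.0) ** 2) / (2 * 3.0**2))
        y_c = bump(t_c) * 0 + rng.normal(0, 0.3, 60)
        y_d = rng.normal(0, 0.3, 40)  # the bump died out before sampling
        pair = TimeCoursePair(t_c, y_c, t_d, y_d)
        res = analyze_spot(pair, seed=1)
        below = res.posterior[res.tau_grid < 18.0]
        # no grid point below 18 dominates: mass is spread, not spiked
        assert below.max() < 0.5

    def test_null_lr_within_band(self):
        """Matched null courses: LR <= 1.05 in >=90% of replicates."""
        ok = 0
        n_rep = 10
        for seed in range(n_rep):
            pair = make_time_course(30.0, 0.0, seed=100 + seed)
            res = analyze_spot(pair, seed=seed)
            ok += res.likelihood_ratio <= 1.05
        assert ok >= 0.9 * n_rep

    def test_empty_grid_rejected(self):
        pair = make_time_course(30.0, 0.9, seed=7)
        params = fit_hyperparameters(pair, seed=7)
        with pytest.raises(ValueError, match="empty"):
            perturbation_posterior(pair, params, tau_grid=np.array([]))

    def test_minimum_points_enforced(self):
        with pytest.raises(ValueError, match="3 points"):
            TimeCoursePair(np.array([1.0, 2]), np.array([0.0, 1]),
                           np.array([20.0, 30, 40]), np.zeros(3))
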