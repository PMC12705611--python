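"""GP regressor, CRPS and NRMSE contracts, checked against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from phenoloop.gp import (
    DEFAULT_GRID,
    GPConfig,
    GPDoseResponse,
    crps_gaussian,
    fit_gp,
    nrmse,
)


def dense_posterior_oracle(X, y, Xs, sv, ls, nv, kind="rbf", prior_mean=0.0):
    """Independent GP conditional via explicit kernel-matrix inversion."""
    X = np.atleast_2d(np.asarray(X, float).T).T
    Xs = np.atleast_2d(np.asarray(Xs, float).T).T
    ls = np.atleast_1d(np.asarray(ls, float))

    def k(A, B):
        d2 = np.sum(((A[:, None, :] - B[None, :, :]) / ls) ** 2, axis=-1)
        if kind == "rbf":
            return sv * np.exp(-0.5 * d2)
        r = np.sqrt(3.0 * d2)
        return sv * (1.0 + r) * np.exp(-r)

    K = k(X, X) + nv * np.eye(len(X))
    Ks = k(Xs, X)
    Kinv = np.linalg.inv(K)
    mu = prior_mean + Ks @ Kinv @ (y - prior_mean)
    var = sv - np.sum((Ks @ Kinv) * Ks, axis=1)
    return mu, np.sqrt(np.maximum(var, 0.0))


class TestPredict:
    @pytest.mark.parametrize("kernel", ["rbf", "matern32"])
    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_matches_dense_oracle(self, kernel, n):
        rng = np.random.default_rng(n * 7 + (kernel == "rbf"))
        X = rng.uniform(0, 500, n)
        y = rng.normal(0, 1, n)
        theta = dict(signal_variance=1.7, lengthscales=[90.0], noise_variance=0.2)
        m = GPDoseResponse(kernel=kernel, hyperparameters=theta, optimize=False,
                          prior_mean="zero").fit(X, y)
        Xs = rng.uniform(0, 500, 25)
        mu, sd = m.predict(Xs, return_std=True)
        mu_o, sd_o = dense_posterior_oracle(X, y, Xs, 1.7, 90.0, 0.2, kernel)
        assert np.max(np.abs(mu - mu_o)) < 1e-8
        assert np.max(np.abs(sd - sd_o)) < 1e-8

    def test_two_point_hand_oracle(self):
        # fully hand-computable 2x2 instance
        theta = dict(signal_variance=2.0, lengthscales=[1.5], noise_variance=0.3)
        m = GPDoseResponse(hyperparameters=theta, optimize=False,
                          prior_mean="zero").fit([0.0, 2.0], [1.0, -1.0])
        mu, sd = m.predict([0.5, 3.0], return_std=True)
        k = lambda a, b: 2.0 * np.exp(-0.5 * ((a - b) / 1.5) ** 2)  # noqa: E731
        K = np.array([[k(0, 0) + 0.3, k(0, 2)], [k(2, 0), k(2, 2) + 0.3]])
        Ks = np.array([[k(0.5, 0), k(0.5, 2)], [k(3, 0), k(3, 2)]])
        mu_o = Ks @ np.linalg.inv(K) @ np.array([1.0, -1.0])
        var_o = 2.0 - np.sum((Ks @ np.linalg.inv(K)) * Ks, axis=1)
        assert np.allclose(mu, mu_o, atol=1e-8)
        assert np.allclose(sd, np.sqrt(var_o), atol=1e-8)

    def test_near_interpolation_at_training_point(self):
        theta = dict(signal_variance=1.0, lengthscales=[50.0], noise_variance=1e-12)
        m = GPDoseResponse(hyperparameters=theta, optimize=False).fit([100.0, 300.0],
                                                                      [2.0, 1.0])
        mu, sd = m.predict([100.0], return_std=True)
        assert mu[0] == pytest.approx(2.0, abs=1e-4)
        assert sd[0] < 1e-3

    def test_empty_training_returns_prior(self):
        theta = dict(signal_variance=4.0, lengthscales=[50.0], noise_variance=0.0)
        m = GPDoseResponse(hyperparameters=theta, optimize=False).fit(
            np.empty((0, 1)), np.empty(0))
        mu, sd = m.predict([0.0, 250.0], return_std=True)
        assert np.allclose(mu, 0.0)
        assert np.allclose(sd, 2.0)

    def test_sd_with_noise_dominates(self, harvest):
        m = fit_gp(harvest.dose_uM.to_numpy(), harvest.fw_root.to_numpy(),
                   GPConfig(max_iterations=200, seed=0))
        ps = m.posterior_summary()
        assert ps.grid.shape == DEFAULT_GRID.shape
        assert np.all(ps.sd_with_noise >= ps.sd_epistemic)

    def test_variance_shrinks_with_added_point(self):
        theta = dict(signal_variance=1.0, lengthscales=[80.0], noise_variance=0.05)
        grid = np.linspace(0, 500, 51)
        base = GPDoseResponse(hyperparameters=theta, optimize=False).fit(
            [0.0, 500.0], [0.1, -0.2])
        _, sd0 = base.predict(grid, return_std=True)
        more = GPDoseResponse(hyperparameters=theta, optimize=False).fit(
            [0.0, 500.0, 250.0], [0.1, -0.2, 0.3])
        _, sd1 = more.predict(grid, return_std=True)
        assert np.all(sd1 <= sd0 + 1e-12)


class TestFit:
    def test_deterministic_given_seed(self, harvest):
        cfg = GPConfig(max_iterations=300, seed=11)
        a = fit_gp(harvest.dose_uM.to_numpy(), harvest.fw_root.to_numpy(), cfg)
        b = fit_gp(harvest.dose_uM.to_numpy(), harvest.fw_root.to_numpy(), cfg)
        assert a.signal_variance_ == b.signal_variance_
        assert np.array_equal(a.lengthscales_, b.lengthscales_)
        assert a.noise_variance_ == b.noise_variance_

    def test_constant_target_degenerates_gracefully(self):
        m = GPDoseResponse(max_iterations=200).fit(np.arange(6.0), np.full(6, 3.0))
        assert m.signal_variance_ < 1e-10
        assert np.allclose(m.predict(np.linspace(0, 5, 11)), 3.0, atol=1e-6)

    def test_constant_input_column_named_in_error(self):
        X = np.column_stack([np.arange(6.0), np.full(6, 2.0)])
        with pytest.raises(ValueError, match="column 1"):
            GPDoseResponse(max_iterations=50).fit(X, np.arange(6.0))

    def test_fitted_beats_random_inbounds_draws(self, harvest):
        X = harvest.dose_uM.to_numpy()
        y = harvest.fw_root.to_numpy()
        m = fit_gp(X, y, GPConfig(max_iterations=400, seed=5))
        lb, ub = m._bounds_
        rng = np.random.default_rng(123)
        for _ in range(100):
            t = rng.uniform(lb, ub)
            lml = m.log_marginal_likelihood(dict(signal_variance=np.exp(t[0]),
                                                 lengthscales=np.exp(t[1:-1]),
                                                 noise_variance=np.exp(t[-1])))
            assert m.log_marginal_likelihood_ >= lml - 1e-9

    def test_lengthscale_recovery_from_prior_draw(self):
        # noiseless draw from the prior at known lengthscale
        rng = np.random.default_rng(4)
        X = np.sort(rng.uniform(0, 500, 40))
        ls_true = 80.0
        K = 1.0 * np.exp(-0.5 * ((X[:, None] - X[None, :]) / ls_true) ** 2)
        y = np.linalg.cholesky(K + 1e-10 * np.eye(40)) @ rng.standard_normal(40)
        m = fit_gp(X, y, GPConfig(max_iterations=800, seed=1))
        assert abs(np.log(m.lengthscales_[0]) - np.log(ls_true)) \
            <= 0.5 * np.log(ls_true)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            GPDoseResponse().fit([1.0], [2.0])

    def test_json_round_trip(self, harvest, tmp_path):
        m = fit_gp(harvest.dose_uM.to_numpy(), harvest.fw_root.to_numpy(),
                   GPConfig(max_iterations=150, seed=0))
        m.to_json(tmp_path / "model.json")
        back = GPDoseResponse.from_json(tmp_path / "model.json")
        grid = np.linspace(0, 500, 21)
        mu_a, sd_a = m.predict(grid, return_std=True)
        mu_b, sd_b = back.predict(grid, return_std=True)
        assert np.allclose(mu_a, mu_b) and np.allclose(sd_a, sd_b)


def crps_numeric(mu, sigma, y):
    """Oracle: integrate (F(t) - 1{t >= y})^2 dt directly."""
    lo = min(mu - 12 * sigma, y - 1.0)
    hi = max(mu + 12 * sigma, y + 1.0)

    def integrand(t):
        return (norm.cdf((t - mu) / sigma) - (t >= y)) ** 2

    val, _ = quad(integrand, lo, hi, limit=400)
    return val


class TestCrps:
    def test_centered_unit_value(self):
        # numeric integration gives 2*phi(0) - 1/sqrt(pi) = 0.23370
        assert crps_gaussian(0.0, 1.0, 0.0) == pytest.approx(0.23370, abs=1e-5)

    def test_point_mass_limit(self):
        assert crps_gaussian(1.0, 0.0, 3.5) == pytest.approx(2.5)

    @pytest.mark.parametrize("z", [-10.0, -2.0, 0.0, 0.7, 3.0, 10.0])
    @pytest.mark.parametrize("sigma", [0.3, 1.0, 4.0])
    def test_matches_numeric_integral(self, z, sigma):
        mu, y = 0.5, 0.5 + z * sigma
        assert crps_gaussian(mu, sigma, y) == pytest.approx(
            crps_numeric(mu, sigma, y), abs=1e-6)

    def test_large_z_asymptote(self):
        # CRPS -> |y - mu| - sigma/sqrt(pi); within 1% of |y-mu| at z = 100
        val = crps_gaussian(0.0, 1.0, 100.0)
        assert abs(val - 100.0) / 100.0 < 0.01

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            crps_gaussian(0.0, -1.0, 0.0)


class TestNrmse:
    def test_perfect_prediction(self):
        assert nrmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_example(self):
        assert nrmse([1.0, 1.0], [0.0, 2.0]) == pytest.approx(0.5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        obs = rng.normal(0, 1, 30)
        pred = obs + rng.normal(0, 0.3, 30)
        a, b = 4.2, -1.3
        base = nrmse(pred, obs)
        scaled = nrmse(a * pred + b, a * obs + b)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            nrmse([1.0, 2.0], [3.0, 3.0])
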