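import math

import numpy as np
import pytest
from scipy import stats

from orthokinetics.gp import (DT_BOUNDS, EPS_NOISE, TIME_SCALE, HyperParams,
                              NeuralNetGP, TimeShiftGP, _nn_gram,
                              bayes_factor_pair, default_dt_grid, fit_gp_map,
                              fit_shared, gp_log_marginal, gp_predict,
                              hyperprior_logdensity,
                              noise_mode_from_replicates, standardize_profile,
                              nn_covariance)
from orthokinetics.simulate import DEFAULT_TIMEPOINTS, latent_profile

GRID = np.asarray(DEFAULT_TIMEPOINTS)


class TestStandardize:
    def test_mean_zero_sd_one_order_preserved(self):
        z = standardize_profile([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)
        assert np.all(np.diff(z) > 0)

    def test_idempotent(self):
        z = standardize_profile(np.random.default_rng(0).normal(size=20))
        np.testing.assert_allclose(standardize_profile(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_profile([5.0, 5.0, 5.0])


class TestNNCovariance:
    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x, x2 = rng.uniform(-1, 2, size=2)
            l, sf2 = rng.uniform(0.05, 3), rng.uniform(0.1, 3)
            assert nn_covariance(x, x2, l, sf2) == pytest.approx(
                nn_covariance(x2, x, l, sf2)
            )

    def test_long_length_scale_limit(self):
        assert abs(nn_covariance(0.3, 0.7, l=1e6, sf2=1.0)) < 1e-9

    def test_hand_evaluated_value_at_origin(self):
        # x = x' = 0, l = sf2 = 1: k = asin( 1 / sqrt(2 * 2) ) = asin(1/2)
        assert nn_covariance(0.0, 0.0, 1.0, 1.0) == pytest.approx(
            math.asin(0.5)
        )
        assert nn_covariance(0.0, 0.0, 1.0, 1.0) == pytest.approx(0.5235987, abs=1e-6)

    def test_bounded_by_half_pi_times_sf2(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, x2 = rng.uniform(-5, 5, 2)
            sf2 = rng.uniform(0.1, 4)
            k = nn_covariance(x, x2, rng.uniform(0.05, 2), sf2)
            assert abs(k) <= sf2 * math.pi / 2 + 1e-12

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            nn_covariance(0.0, 1.0, l=-1.0, sf2=1.0)

    def test_gram_nearly_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            xs = rng.uniform(0, 1.5, size=rng.integers(3, 15))
            K = _nn_gram(xs, rng.uniform(0.05, 2), rng.uniform(0.1, 3))
            np.testing.assert_allclose(K, K.T, atol=1e-12)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestLogMarginal:
    def test_scalar_closed_form(self):
        h = HyperParams(0.3, 0.8, 0.2)
        x, y = 12.0, 0.7
        var = nn_covariance(x / TIME_SCALE, x / TIME_SCALE, h.l, h.sf2) + h.sn2
        expected = stats.norm.logpdf(y, 0.0, math.sqrt(var))
        assert gp_log_marginal([x], [y], h) == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            xs = rng.uniform(0, 72, n)
            h = HyperParams(l=rng.uniform(0.05, 2), sf2=rng.uniform(0.1, 3),
                            sn2=rng.uniform(0.01, 1.0))
            y = rng.normal(size=n)
            K = _nn_gram(xs / TIME_SCALE, h.l, h.sf2) + h.sn2 * np.eye(n)
            oracle = stats.multivariate_normal(np.zeros(n), K).logpdf(y)
            assert gp_log_marginal(xs, y, h) == pytest.approx(oracle, abs=1e-8)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(5)
        xs = rng.uniform(0, 72, 12)
        y = rng.normal(size=12)
        h = HyperParams(0.2, 1.0, 0.1)
        perm = rng.permutation(12)
        assert gp_log_marginal(xs, y, h) == pytest.approx(
            gp_log_marginal(xs[perm], y[perm], h), abs=1e-10
        )


class TestHyperprior:
    def test_sf2_mode_near_point_nine(self):
        # 1-D grid oracle over sf2 under the shape-rate reading of Gamma(10,10)
        grid = np.linspace(0.05, 3.0, 600)
        dens = [
            hyperprior_logdensity(HyperParams(0.2, v, 0.1), noise_mode=0.1)
            for v in grid
        ]
        assert grid[int(np.argmax(dens))] == pytest.approx(0.9, abs=0.01)

    def test_sn2_outside_support(self):
        h = HyperParams.__new__(HyperParams)  # bypass validation
        object.__setattr__(h, "l", 0.2)
        object.__setattr__(h, "sf2", 1.0)
        object.__setattr__(h, "sn2", 1.5)
        object.__setattr__(h, "dt", None)
        assert hyperprior_logdensity(h, 0.1) == -np.inf

    def test_finite_on_admissible_box(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            h = HyperParams(l=rng.uniform(0.01, 5), sf2=rng.uniform(0.01, 5),
                            sn2=rng.uniform(EPS_NOISE, 1.0),
                            dt=rng.uniform(*DT_BOUNDS))
            v = hyperprior_logdensity(h, noise_mode=rng.uniform(0.01, 1.0))
            assert np.isfinite(v)

    def test_noise_prior_mode_honored(self):
        # density over sn2 peaks at the requested mode (shape 2, rate 1/mode)
        mode = 0.3
        grid = np.linspace(0.01, 0.99, 500)
        dens = [
            hyperprior_logdensity(HyperParams(0.2, 0.9, v), noise_mode=mode)
            for v in grid
        ]
        assert grid[int(np.argmax(dens))] == pytest.approx(mode, abs=0.01)


class TestFitAndPredict:
    def _smooth_profile(self, seed=0, noise=0.05):
        rng = np.random.default_rng(seed)
        f = latent_profile(rng, GRID)
        X = np.repeat(GRID, 3)
        y = f(X) + rng.normal(0, noise, X.size)
        return X, standardize_profile(y)

    def test_map_dominates_hyperparameter_grid(self):
        X, y = self._smooth_profile(seed=1)
        nm = noise_mode_from_replicates(y.reshape(10, 3))
        fit = fit_gp_map(X, y, noise_mode=nm, restarts=3, seed=0)
        ls = np.geomspace(0.02, 5, 12)
        sf2s = np.geomspace(0.05, 5, 12)
        sn2s = np.geomspace(EPS_NOISE * 1.01, 0.99, 12)
        best_grid = -np.inf
        for l in ls:
            for sf2 in sf2s:
                for sn2 in sn2s:
                    h = HyperParams(l, sf2, sn2)
                    v = gp_log_marginal(X, y, h) + hyperprior_logdensity(h, nm)
                    best_grid = max(best_grid, v)
        assert fit.log_map_objective >= best_grid - 1e-6

    def test_pure_noise_fits_large_noise_variance(self):
        rng = np.random.default_rng(7)
        X = np.repeat(GRID, 3)
        y = standardize_profile(rng.normal(size=30))
        nm = noise_mode_from_replicates(y.reshape(10, 3))
        fit = fit_gp_map(X, y, noise_mode=nm, restarts=3, seed=1)
        assert fit.hyperparams.sn2 >= 0.5

    def test_deterministic_for_seed(self):
        X, y = self._smooth_profile(seed=2)
        f1 = fit_gp_map(X, y, noise_mode=0.05, restarts=3, seed=9)
        f2 = fit_gp_map(X, y, noise_mode=0.05, restarts=3, seed=9)
        assert f1.hyperparams == f2.hyperparams
        assert f1.log_marginal == f2.log_marginal

    def test_predict_interpolates_training_data(self):
        # near-noiseless data: posterior mean at training points ~ targets
        X, y = self._smooth_profile(seed=3, noise=1e-3)
        fit = fit_gp_map(X, y, noise_mode=0.001, restarts=2, seed=0)
        mu, var = gp_predict(fit, GRID)
        means = y.reshape(10, 3).mean(axis=1)
        np.testing.assert_allclose(mu, means, atol=0.05)
        # predictive variance at training points bounded by noise level
        assert (var <= fit.hyperparams.sn2 + 1e-6).all()

    def test_predict_matches_direct_solve(self):
        X, y = self._smooth_profile(seed=4)
        fit = fit_gp_map(X, y, noise_mode=0.05, restarts=2, seed=0)
        h = fit.hyperparams
        xs = X / TIME_SCALE
        x_star = np.array([3.0, 30.0, 66.0])
        K = _nn_gram(xs, h.l, h.sf2) + h.sn2 * np.eye(len(xs))
        k_star = np.array([
            [nn_covariance(a, b / TIME_SCALE, h.l, h.sf2) for b in x_star]
            for a in xs
        ])
        mu_oracle = k_star.T @ np.linalg.solve(K, y)
        var_oracle = np.array([
            nn_covariance(b / TIME_SCALE, b / TIME_SCALE, h.l, h.sf2)
            for b in x_star
        ]) - np.einsum("ij,ij->j", k_star, np.linalg.solve(K, k_star))
        mu, var = gp_predict(fit, x_star)
        np.testing.assert_allclose(mu, mu_oracle, atol=1e-8)
        np.testing.assert_allclose(var, var_oracle, atol=1e-8)

    def test_predict_empty_input(self):
        X, y = self._smooth_profile(seed=5)
        fit = fit_gp_map(X, y, noise_mode=0.05, restarts=1, seed=0)
        mu, var = gp_predict(fit, [])
        assert mu.size == 0 and var.size == 0

    def test_extrapolation_warns(self):
        X, y = self._smooth_profile(seed=6)
        est = NeuralNetGP(noise_mode=0.05, restarts=1).fit(X.reshape(-1, 1), y)
        with pytest.warns(UserWarning, match="extrapolat"):
            est.predict(np.array([150.0]))

    def test_sklearn_param_interface(self):
        est = NeuralNetGP(noise_mode=0.2, restarts=4, random_state=3)
        params = est.get_params()
        assert params["noise_mode"] == 0.2
        clone = NeuralNetGP(**params)
        assert clone.get_params() == params


class TestFitShared:
    def _pair(self, shift, seed=0, noise=0.1):
        rng = np.random.default_rng(seed)
        f = latent_profile(rng, GRID)
        X = np.repeat(GRID, 3)
        yh = standardize_profile(f(X) + rng.normal(0, noise, X.size))
        ym = standardize_profile(f(X + shift) + rng.normal(0, noise, X.size))
        return X, yh, X, ym

    def test_identical_profiles_pick_zero_shift(self):
        Xh, yh, Xm, ym = self._pair(0.0, seed=1)
        fit = fit_shared(Xh, yh, Xm, yh.copy(), dt_grid=[-12, 0, 12],
                         noise_mode=0.05, seed=0)
        assert fit.hyperparams.dt == 0.0

    def test_known_shift_recovered_within_grid_step(self):
        Xh, yh, Xm, ym = self._pair(12.0, seed=2)
        fit = fit_shared(Xh, yh, Xm, ym, noise_mode=0.05, seed=0)
        assert abs(fit.hyperparams.dt - 12.0) <= 2.0

    def test_singleton_grid_returned(self):
        Xh, yh, Xm, ym = self._pair(0.0, seed=3)
        fit = fit_shared(Xh, yh, Xm, ym, dt_grid=[-6.0], noise_mode=0.05,
                         seed=0)
        assert fit.hyperparams.dt == -6.0

    def test_empty_grid_rejected(self):
        Xh, yh, Xm, ym = self._pair(0.0, seed=4)
        with pytest.raises(ValueError, match="dt_grid"):
            fit_shared(Xh, yh, Xm, ym, dt_grid=[], noise_mode=0.05)

    def test_default_grid_spans_bounds(self):
        grid = default_dt_grid()
        assert grid[0] == -24 and grid[-1] == 24
        assert np.allclose(np.diff(grid), 2.0)


class TestBayesFactorPair:
    def test_duplicated_profile_called_shared(self):
        rng = np.random.default_rng(8)
        f = latent_profile(rng, GRID)
        X = np.repeat(GRID, 3)
        yh = f(X) + rng.normal(0, 0.05, X.size)
        ym = yh + rng.normal(0, 0.05, X.size)
        res = bayes_factor_pair(X, yh, X, ym, seed=0)
        assert res.call == "shared"
        assert res.bf > 10

    def test_noise_vs_signal_called_different(self):
        rng = np.random.default_rng(9)
        X = np.repeat(GRID, 3)
        yh = 1.0 / (1.0 + np.exp(-(X - 12.0) / 4.0)) + rng.normal(0, 0.05, X.size)
        ym = rng.normal(size=X.size)
        res = bayes_factor_pair(X, yh, X, ym, seed=1)
        assert res.call == "different"

    def test_species_swap_symmetric_at_zero_shift(self):
        rng = np.random.default_rng(10)
        f = latent_profile(rng, GRID)
        X = np.repeat(GRID, 3)
        y = f(X) + rng.normal(0, 0.1, X.size)
        a = bayes_factor_pair(X, y, X, y.copy(), dt_grid=[0.0], seed=3)
        b = bayes_factor_pair(X, y.copy(), X, y, dt_grid=[0.0], seed=3)
        assert a.log_bf == pytest.approx(b.log_bf, abs=1e-6)

    def test_invariant_to_common_affine_rescaling(self):
        # a common change of log-expression units must not move the BF;
        # the change-of-variables terms make this exact
        rng = np.random.default_rng(11)
        f = latent_profile(rng, GRID)
        X = np.repeat(GRID, 3)
        yh = f(X) + rng.normal(0, 0.1, X.size)
        ym = f(X) + rng.normal(0, 0.1, X.size)
        base = bayes_factor_pair(X, yh, X, ym, dt_grid=[0.0], seed=4)
        scaled = bayes_factor_pair(X, 3.0 * yh + 5.0, X, 3.0 * ym + 5.0,
                                   dt_grid=[0.0], seed=4)
        # equality up to optimizer finite-difference numerics
        assert base.log_bf == pytest.approx(scaled.log_bf, abs=1e-3)
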