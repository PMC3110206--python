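"""Kernel weights, weighted standardization, elastic-net solver, AICc fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vcgrn import (
    SolverConfig,
    degrees_of_freedom,
    fit_target_sample,
    gaussian_kernel_weights,
    update_adaptive_weights,
    weighted_aicc,
    weighted_elastic_net,
    weighted_standardize,
)
from vcgrn.errors import (
    DegenerateDesign,
    InvalidBandwidth,
    InvalidParameter,
    PseudoinverseFallback,
)
from vcgrn.vc_solver import elastic_net_objective, lambda_max

from conftest import convex_oracle_enet


class TestKernelWeights:
    def test_zero_distance_gives_unit_weight(self):
        m = np.array([0.0, 1.0, -1.0])
        kw = gaussian_kernel_weights(m, 0, h=0.5)
        assert kw.w[0] == 1.0

    def test_one_bandwidth_distance(self):
        m = np.array([0.0, 0.5])
        kw = gaussian_kernel_weights(m, 0, h=0.5)
        assert kw.w[1] == pytest.approx(np.exp(-0.5))

    def test_huge_bandwidth_limit(self):
        m = np.array([0.0, 3.0, -7.0])
        kw = gaussian_kernel_weights(m, 0, h=1e9)
        assert np.allclose(kw.w, 1.0)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(InvalidBandwidth):
            gaussian_kernel_weights(np.array([0.0, 1.0]), 0, h=0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0.05, 10.0), st.integers(0, 2**31 - 1))
    def test_symmetry_and_monotonicity(self, h, seed):
        m = np.random.default_rng(seed).uniform(-3, 3, 25)
        kw = gaussian_kernel_weights(m, 0, h)
        d = np.abs(m - m[0])
        order = np.argsort(d)
        assert np.all(np.diff(kw.w[order]) <= 1e-15)
        # weights are positive in exact arithmetic; far samples may underflow
        assert np.all(kw.w >= 0) and np.all(kw.w <= 1)
        assert kw.w[0] == 1.0


class TestStandardize:
    def test_uniform_weights_moments(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.array([[1.0], [2.0], [3.0]])
        w = np.ones(3)
        y_s, X_s, rec = weighted_standardize(y, X, w)
        assert abs(y_s.mean()) < 1e-14
        assert y_s.var() == pytest.approx(1.0)
        assert abs(X_s[:, 0].mean()) < 1e-14
        assert X_s[:, 0].var() == pytest.approx(1.0)

    def test_weighted_moments(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 3))
        w = rng.uniform(0.1, 1.0, 30)
        y_s, X_s, _ = weighted_standardize(y, X, w)
        wn = w / w.sum()
        assert abs(wn @ y_s) < 1e-12
        assert wn @ y_s**2 == pytest.approx(1.0)
        for j in range(3):
            assert abs(wn @ X_s[:, j]) < 1e-12
            assert wn @ X_s[:, j] ** 2 == pytest.approx(1.0)

    def test_constant_column_dropped_and_recorded(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            _, X_s, rec = weighted_standardize(y, X, np.ones(3))
        assert rec.dropped == [0]
        assert X_s.shape == (3, 1)

    def test_all_degenerate_raises(self):
        with pytest.raises(DegenerateDesign):
            weighted_standardize(np.arange(3.0), np.ones((3, 2)), np.ones(3))

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(20)
        X = rng.standard_normal((20, 2))
        w = rng.uniform(0.2, 1.0, 20)
        y1, X1, _ = weighted_standardize(y, X, w)
        y2, X2, _ = weighted_standardize(y1, X1, w)
        assert np.allclose(y1, y2, atol=1e-12)
        assert np.allclose(X1, X2, atol=1e-12)


class TestElasticNet:
    def test_lambda_max_gives_exact_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        w = rng.uniform(0.2, 1.0, 20)
        gamma = rng.uniform(0.5, 2.0, 5)
        lmax = lambda_max(y, X, w, gamma)
        beta = weighted_elastic_net(y, X, w, lmax, 0.1, gamma)
        assert np.all(beta == 0.0)
        # and just below the boundary the model is nonempty
        beta2 = weighted_elastic_net(y, X, w, 0.99 * lmax, 0.1, gamma)
        assert np.any(beta2 != 0.0)

    def test_unpenalized_orthonormal_equals_least_squares(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((30, 4))
        Q, _ = np.linalg.qr(A)
        y = rng.standard_normal(30)
        beta = weighted_elastic_net(y, Q, np.ones(30), 0.0, 0.0)
        assert np.allclose(beta, Q.T @ y, atol=1e-10)

    def test_matches_convex_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        w = rng.uniform(0.3, 1.0, 12)
        beta = weighted_elastic_net(y, X, w, 0.1, 0.05, tol=1e-12)
        oracle = convex_oracle_enet(y, X, w, 0.1, 0.05, np.ones(4))
        assert np.max(np.abs(beta - oracle)) < 1e-6

    def test_grouping_effect_identical_columns(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        X = np.column_stack([x, x, rng.standard_normal(40)])
        y = 2 * x + rng.standard_normal(40) * 0.1
        beta = weighted_elastic_net(y, X, np.ones(40), 0.05, 0.5, tol=1e-12)
        assert abs(beta[0] - beta[1]) < 1e-8

    def test_negative_penalty_rejected(self):
        with pytest.raises(InvalidParameter):
            weighted_elastic_net(np.ones(3), np.ones((3, 1)), np.ones(3),
                                 -1.0, 0.0)


class TestAdaptiveWeights:
    def test_zero_coefficient_huge_weight(self):
        gamma = update_adaptive_weights(np.array([0.0]), 1e-10)
        assert gamma[0] == pytest.approx(1e10)

    def test_arithmetic(self):
        gamma = update_adaptive_weights(np.array([1.0, 0.5]), 1e-14)
        assert np.allclose(gamma, [1.0, 2.0])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_homogeneity(self, c):
        beta = np.array([1.0, -0.25, 3.0])
        g1 = update_adaptive_weights(beta, 1e-14)
        g2 = update_adaptive_weights(c * beta, 1e-14)
        assert np.allclose(g2, g1 / c, rtol=1e-6)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(InvalidParameter):
            update_adaptive_weights(np.ones(2), 0.0)


class TestDegreesOfFreedom:
    def test_unpenalized_full_rank_projection(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 3))
        w = rng.uniform(0.2, 1.0, 20)
        assert degrees_of_freedom(X, w, 0.0) == pytest.approx(3.0)

    def test_infinite_ridge_limit(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 3))
        assert degrees_of_freedom(X, np.ones(20), 1e12) < 1e-8

    def test_matches_spectral_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 3))
        w = rng.uniform(0.1, 1.0, 20)
        lam2 = 0.5
        d = np.linalg.svd(np.sqrt(w)[:, None] * X, compute_uv=False)
        oracle = np.sum(d**2 / (d**2 + lam2))
        assert degrees_of_freedom(X, w, lam2) == pytest.approx(oracle, abs=1e-10)

    def test_collinear_unpenalized_falls_back_to_pinv(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(PseudoinverseFallback):
            df = degrees_of_freedom(X, np.ones(10), 0.0)
        assert df == pytest.approx(1.0, abs=1e-8)


class TestWeightedAicc:
    def test_doubling_rss_adds_n_log_2(self):
        n_eff, df = 50.0, 3.0
        s1 = weighted_aicc(10.0, df, n_eff)
        s2 = weighted_aicc(20.0, df, n_eff)
        assert s2 - s1 == pytest.approx(n_eff * np.log(2.0))

    def test_inadmissible_model_scores_infinity(self):
        assert weighted_aicc(1.0, 49.0, 50.0) == np.inf
        assert weighted_aicc(1.0, 50.0, 50.0) == np.inf

    def test_direct_formula(self):
        rss, df, n = 3.7, 2.5, 41.0
        expected = n * np.log(rss / n) + 2 * df * n / (n - df - 1)
        assert weighted_aicc(rss, df, n) == pytest.approx(expected)

    def test_nonpositive_rss_rejected(self):
        with pytest.raises(InvalidParameter):
            weighted_aicc(0.0, 1.0, 10.0)


class TestFitTargetSample:
    def _sparse_instance(self, seed, n=150, q=12, noise_sd=0.2):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, q))
        beta_true = np.zeros(q)
        beta_true[[1, 4, 7]] = [1.0, -0.8, 0.5]
        y = X @ beta_true + noise_sd * rng.standard_normal(n)
        return y, X, beta_true

    def test_sparse_truth_support_recovered(self):
        exact = 0
        for seed in range(10):
            y, X, beta_true = self._sparse_instance(seed=seed)
            fit = fit_target_sample(y, X, np.ones(len(y)))
            truth = set(np.flatnonzero(beta_true))
            support = set(np.flatnonzero(fit.beta))
            assert truth <= support  # true predictors never missed
            assert np.allclose(fit.beta[[1, 4, 7]], beta_true[[1, 4, 7]],
                               atol=0.1)
            exact += support == truth
        assert exact >= 7  # exact recovery in the large majority of seeds

    def test_pure_noise_support_stays_small(self):
        # y independent of X: spurious support should be rare and tiny.
        sizes = []
        for seed in range(15):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((150, 12))
            y = rng.standard_normal(150)
            fit = fit_target_sample(y, X, np.ones(150))
            sizes.append(int(np.count_nonzero(fit.beta)))
        assert np.median(sizes) <= 1
        assert max(sizes) <= 5

    def test_single_iteration_is_plain_grid_search(self):
        y, X, _ = self._sparse_instance(seed=101)
        fit = fit_target_sample(y, X, np.ones(len(y)),
                                SolverConfig(max_iter=1))
        assert fit.iterations_used == 1
        assert np.all(fit.gamma == 1.0)

    def test_recursion_never_worse_than_first_iteration(self):
        for seed in (102, 103, 104):
            y, X, _ = self._sparse_instance(seed=seed)
            one = fit_target_sample(y, X, np.ones(len(y)),
                                    SolverConfig(max_iter=1))
            full = fit_target_sample(y, X, np.ones(len(y)),
                                     SolverConfig(max_iter=10))
            assert full.aicc <= one.aicc + 1e-12

    def test_adaptive_recursion_sharpens_support(self):
        # full recursion has no more false positives than one iteration
        worse = 0
        for seed in range(20):
            y, X, beta_true = self._sparse_instance(seed=300 + seed)
            truth = set(np.flatnonzero(beta_true))
            one = fit_target_sample(y, X, np.ones(len(y)),
                                    SolverConfig(max_iter=1))
            full = fit_target_sample(y, X, np.ones(len(y)))
            fp_one = len(set(np.flatnonzero(one.beta)) - truth)
            fp_full = len(set(np.flatnonzero(full.beta)) - truth)
            if fp_full > fp_one:
                worse += 1
        assert worse <= 1  # non-increasing in >= 95% of replicates

    def test_raw_scale_prediction(self):
        # coefficients map back to the raw scale: predictions approximate y
        y, X, _ = self._sparse_instance(seed=105, noise_sd=0.1)
        y_shifted = 5.0 + 2.0 * y
        fit = fit_target_sample(y_shifted, X, np.ones(len(y)))
        resid = y_shifted - fit.predict(X)
        assert np.sqrt(np.mean(resid**2)) < 0.5

    def test_objective_never_above_oracle(self):
        # solver solutions are optimal for their own (lam1, lam2, gamma)
        rng = np.random.default_rng(9)
        for _ in range(25):
            n, q = int(rng.integers(10, 30)), int(rng.integers(2, 7))
            X = rng.standard_normal((n, q))
            y = rng.standard_normal(n)
            w = rng.uniform(0.1, 1.0, n)
            lam1 = float(rng.uniform(0.01, 0.4))
            lam2 = float(rng.uniform(0.0, 0.4))
            gamma = rng.uniform(0.5, 2.0, q)
            beta = weighted_elastic_net(y, X, w, lam1, lam2, gamma, tol=1e-12)
            oracle = convex_oracle_enet(y, X, w, lam1, lam2, gamma)
            mine = elastic_net_objective(beta, y, X, w, lam1, lam2, gamma)
            best = elastic_net_objective(oracle, y, X, w, lam1, lam2, gamma)
            assert mine <= best + 1e-8
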