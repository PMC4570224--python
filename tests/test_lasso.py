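from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episense import (
    estimate_lambda,
    fit_lasso,
    generate_snp_matrix,
    penalty_scale,
    sample_bd_model,
    sample_mafs,
    shrink,
    simulate_phenotypes,
)
from episense.genotypes import standardize_lenient
from episense.lasso import kkt_violation


def _standardized_design(n, q, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, q))
    A -= A.mean(axis=0)
    A /= A.std(axis=0)
    return A


class TestShrink:
    @pytest.mark.parametrize(
        "v,lam,expected",
        [(2.0, 0.5, 1.5), (-2.0, 0.5, -1.5), (0.3, 0.5, 0.0), (-0.5, 0.5, 0.0), (0.0, 0.0, 0.0)],
    )
    def test_branches(self, v, lam, expected):
        assert shrink(v, lam) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink(1.0, -0.1)

    @given(
        v=st.floats(-1e6, 1e6, allow_nan=False),
        lam=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_odd_and_nonexpansive(self, v, lam):
        assert shrink(-v, lam) == -shrink(v, lam)
        assert abs(shrink(v, lam)) <= abs(v)


class TestFitLasso:
    def test_zero_penalty_matches_least_squares(self):
        A = _standardized_design(60, 8, 0)
        rng = np.random.default_rng(1)
        y = A @ rng.normal(size=8) + 0.1 * rng.normal(size=60)
        fit = fit_lasso(A, y, lam=0.0, tol=1e-12, max_sweeps=20_000)
        beta_ols = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.x_hat, beta_ols, atol=1e-6)

    def test_full_shrinkage_gives_exact_zero(self):
        A = _standardized_design(40, 6, 2)
        y = np.random.default_rng(3).normal(size=40)
        lam_max = np.abs(A.T @ y).max() / 40
        fit = fit_lasso(A, y, lam=lam_max * 1.001)
        assert np.all(fit.x_hat == 0.0)
        assert fit.support.size == 0

    def test_planted_support_recovered_noiseless(self):
        A = _standardized_design(50, 10, 4)
        x_true = np.zeros(10)
        x_true[[1, 4, 7]] = [1.0, -0.8, 0.6]
        y = A @ x_true
        fit = fit_lasso(A, y, lam=0.02, tol=1e-10)
        np.testing.assert_array_equal(fit.support, [1, 4, 7])

    def test_objective_trace_monotone(self):
        A = _standardized_design(80, 30, 5)
        rng = np.random.default_rng(6)
        y = A[:, :4] @ rng.normal(size=4) + rng.normal(size=80)
        fit = fit_lasso(A, y, lam=0.05)
        assert np.all(np.diff(fit.objective_trace) <= 1e-12)

    def test_kkt_conditions_at_convergence(self):
        A = _standardized_design(60, 12, 7)
        rng = np.random.default_rng(8)
        y = A[:, :3] @ np.array([1.0, -1.0, 0.5]) + 0.3 * rng.normal(size=60)
        lam = 0.1
        fit = fit_lasso(A, y, lam=lam, tol=1e-4)
        assert kkt_violation(A, y, fit) <= 10 * 1e-4

    def test_support_is_exact_nonzeros(self):
        A = _standardized_design(50, 15, 9)
        y = np.random.default_rng(10).normal(size=50)
        fit = fit_lasso(A, y, lam=0.08)
        np.testing.assert_array_equal(fit.support, np.nonzero(fit.x_hat)[0])

    def test_warm_start_reaches_same_solution(self):
        A = _standardized_design(70, 20, 11)
        rng = np.random.default_rng(12)
        y = A[:, :3] @ rng.normal(size=3) + 0.2 * rng.normal(size=70)
        cold = fit_lasso(A, y, lam=0.05, tol=1e-10)
        warm = fit_lasso(A, y, lam=0.05, tol=1e-10, x0=rng.normal(size=20))
        np.testing.assert_allclose(cold.x_hat, warm.x_hat, atol=1e-6)

    def test_nonfinite_rejected(self):
        A = _standardized_design(10, 3, 13)
        y = np.full(10, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso(A, y, lam=0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beats_best_subset_objective(self, seed):
        """The LASSO minimizer's objective never exceeds that of the best
        support-constrained least-squares solution (brute force, |S| <= 3)."""
        rng = np.random.default_rng(seed)
        n, q = 40, 12
        A = _standardized_design(n, q, seed + 100)
        x_true = np.zeros(q)
        x_true[rng.choice(q, 3, replace=False)] = rng.normal(size=3)
        y = A @ x_true + 0.2 * rng.normal(size=n)
        lam = 0.1
        fit = fit_lasso(A, y, lam=lam, tol=1e-10, max_sweeps=20_000)

        def objective(x):
            r = y - A @ x
            return 0.5 * (r @ r) / n + lam * np.abs(x).sum()

        best = objective(np.zeros(q))
        for size in (1, 2, 3):
            for supp in combinations(range(q), size):
                S = list(supp)
                coef, *_ = np.linalg.lstsq(A[:, S], y, rcond=None)
                x = np.zeros(q)
                x[S] = coef
                best = min(best, objective(x))
        assert objective(fit.x_hat) <= best + 1e-8

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_sklearn(self, seed):
        """Independent cross-check against scikit-learn's LASSO solver
        (same objective convention: (1/2n)||y - Ax||^2 + lam||x||_1)."""
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(seed)
        n, q = 100, 25
        A = _standardized_design(n, q, seed + 50)
        y = A[:, :4] @ rng.normal(size=4) + 0.5 * rng.normal(size=n)
        lam = 0.07
        ours = fit_lasso(A, y, lam=lam, tol=1e-12, max_sweeps=50_000)
        ref = sklearn_linear.Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=50_000)
        ref.fit(A, y)
        np.testing.assert_allclose(ours.x_hat, ref.coef_, atol=1e-5)


class TestEstimateLambda:
    def test_purely_linear_model_gives_noise_var(self):
        maf = sample_mafs(200, 0)
        gm = generate_snp_matrix(400, 200, maf, 1)
        model = sample_bd_model(4, 200, 2)
        model.beta = np.zeros_like(model.beta)
        model.gamma = np.zeros_like(model.gamma)
        ph = simulate_phenotypes(model, gm, 3)
        lam = estimate_lambda(gm, ph.y, noise_var=0.3, epsilon=ph.epsilon)
        assert abs(lam - 0.3) < 0.03

    def test_real_mode_multiplier(self):
        maf = sample_mafs(100, 4)
        gm = generate_snp_matrix(200, 100, maf, 5)
        model = sample_bd_model(3, 100, 6)
        ph = simulate_phenotypes(model, gm, 7)
        lam_syn = estimate_lambda(gm, ph.y, 0.3, mode="synthetic", epsilon=ph.epsilon)
        lam_real = estimate_lambda(
            gm, ph.y, 0.3, mode="real", real_factor=2.0, epsilon=ph.epsilon
        )
        assert lam_real == pytest.approx(2.0 * lam_syn)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            penalty_scale(0.0, 100, 10)
        maf = sample_mafs(10, 0)
        gm = generate_snp_matrix(20, 10, maf, 1)
        with pytest.raises(ValueError):
            estimate_lambda(gm, np.zeros(20), noise_var=1.5)
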