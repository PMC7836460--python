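"""ε-SVR: kernel, SMO dual solution vs a generic QP oracle, KKT conditions."""

import numpy as np
import pytest
from scipy.optimize import minimize

from hypredict.models import load_model
from hypredict.svm import (
    SVRConfig,
    SVRParams,
    dual_objective,
    evaluate,
    fit_svr,
    fit_svr_model,
    gaussian_kernel,
    kernel_matrix,
)


def slsqp_dual_oracle(K, y, C, eps):
    """Generic convex-QP solve of the ε-SVR dual over (α⁺, α⁻)."""
    n = len(y)

    def obj(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta - y @ beta + eps * z.sum()

    def grad(z):
        beta = z[:n] - z[n:]
        g = K @ beta
        return np.concatenate([g - y + eps, -g + y + eps])

    cons = [{"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum(),
             "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}]
    res = minimize(
        obj, np.zeros(2 * n), jac=grad, method="SLSQP",
        bounds=[(0, C)] * (2 * n), constraints=cons,
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x[:n] - res.x[n:], res.fun


def full_beta(params: SVRParams, X: np.ndarray) -> np.ndarray:
    """Expand stored support-vector coefficients back onto all samples."""
    beta = np.zeros(len(X))
    for b, sv in zip(params.beta, params.support_vectors):
        i = int(np.argmin(((X - sv) ** 2).sum(axis=1)))
        beta[i] += b
    return beta


class TestKernel:
    def test_identical_points_give_one(self, rng):
        x = rng.normal(size=4)
        assert gaussian_kernel(x, x, gamma=2.0) == 1.0

    def test_unit_distance_unit_gamma(self):
        assert gaussian_kernel(np.array([0.0]), np.array([1.0]), 1.0) == pytest.approx(
            np.exp(-1.0), abs=1e-15
        )

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            assert gaussian_kernel(a, b, 0.7) == gaussian_kernel(b, a, 0.7)


class TestFit:
    def test_constant_targets_inside_tube(self, rng):
        X = rng.normal(size=(15, 2))
        y = np.full(15, 0.4)
        params = fit_svr(X, y, SVRConfig(C=10.0, epsilon=0.05, gamma=0.5))
        assert params.n_sv == 0
        assert params.bias == pytest.approx(0.4, abs=0.05)
        np.testing.assert_allclose(evaluate(params, X), 0.4, atol=0.051)

    def test_near_interpolation_with_zero_epsilon(self, rng):
        # gamma sized so the 1-D kernel matrix stays well conditioned
        X = np.linspace(-1, 1, 12).reshape(-1, 1)
        y = 0.8 * X[:, 0] + rng.normal(0, 0.01, 12)
        cfg = SVRConfig(C=1e4, epsilon=0.0, gamma=10.0, tol=1e-10)
        params = fit_svr(X, y, cfg)
        resid = evaluate(params, X) - y
        assert np.abs(resid).max() < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_matches_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        X = rng.uniform(-1, 1, size=(n, 2))
        y = np.sin(2 * X[:, 0]) + 0.3 * X[:, 1] + rng.normal(0, 0.05, n)
        cfg = SVRConfig(C=10.0, epsilon=0.05, gamma=1.0, tol=1e-10)
        K = kernel_matrix(X, gamma=cfg.gamma)
        params = fit_svr(X, y, cfg)
        beta = full_beta(params, X)
        obj_smo = dual_objective(K, y, beta, cfg.epsilon)
        _, obj_qp = slsqp_dual_oracle(K, y, cfg.C, cfg.epsilon)
        assert obj_smo == pytest.approx(obj_qp, rel=1e-6, abs=1e-8)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_kkt_conditions_hold(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        X = rng.uniform(-1, 1, size=(n, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.1, n)
        cfg = SVRConfig(C=5.0, epsilon=0.08, gamma=0.8, tol=1e-10)
        params = fit_svr(X, y, cfg)
        beta = full_beta(params, X)
        # box and equality feasibility
        assert np.all(np.abs(beta) <= cfg.C + 1e-8)
        assert abs(beta.sum()) < 1e-8
        # points with residual strictly inside the tube carry zero coefficient
        resid = y - evaluate(params, X)
        inside = np.abs(resid) < cfg.epsilon - 1e-4
        assert np.all(np.abs(beta[inside]) < 1e-6)

    def test_more_epsilon_fewer_support_vectors(self, rng):
        n = 30
        X = rng.uniform(-1, 1, size=(n, 1))
        y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.05, n)
        counts = []
        for eps in (0.0, 0.05, 0.15, 0.4):
            params = fit_svr(X, y, SVRConfig(C=10.0, epsilon=eps, gamma=1.0))
            counts.append(params.n_sv)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_svr(np.zeros((1, 2)), np.zeros(1))


class TestPredict:
    def test_no_support_vectors_constant_bias(self):
        params = SVRParams(np.empty(0), np.empty((0, 2)), 0.9, SVRConfig())
        np.testing.assert_allclose(
            evaluate(params, np.random.default_rng(0).normal(size=(5, 2))), 0.9
        )

    def test_agrees_with_naive_summation(self, rng):
        sv = rng.normal(size=(6, 3))
        beta = rng.normal(size=6)
        cfg = SVRConfig(C=1.0, epsilon=0.1, gamma=0.7)
        params = SVRParams(beta, sv, 0.3, cfg)
        X = rng.normal(size=(9, 3))
        naive = np.array([
            sum(beta[j] * gaussian_kernel(X[i], sv[j], cfg.gamma) for j in range(6)) + 0.3
            for i in range(9)
        ])
        np.testing.assert_allclose(evaluate(params, X), naive, atol=1e-12)

    def test_duplicate_rows_identical_predictions(self, small_table, small_split):
        model = fit_svr_model(small_table, small_split,
                              SVRConfig(C=10.0, epsilon=0.01))
        row = small_table.subset([0, 0, 0])
        preds = model.predict(row)
        assert preds[0] == preds[1] == preds[2]

    def test_json_round_trip(self, small_table, small_split, tmp_path):
        model = fit_svr_model(small_table, small_split,
                              SVRConfig(C=10.0, epsilon=0.01))
        p = tmp_path / "svr.json"
        model.save(p)
        again = load_model(p)
        np.testing.assert_allclose(
            again.predict(small_table), model.predict(small_table), atol=1e-12
        )
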