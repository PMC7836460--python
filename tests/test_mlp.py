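"""Perceptron: forward pass, analytic gradients, both trainers."""

import numpy as np
import pytest

from hypredict.data import split_dataset
from hypredict.mlp import (
    MLPParams,
    MLPTrainConfig,
    fit_mlp,
    forward,
    init_mlp,
    logsig,
    residual_jacobian,
    sse_and_gradient,
    train_backprop,
    train_lm,
)
from hypredict.models import load_model
from hypredict.synth import DEFAULT_CONFIG, generate_dataset


def finite_difference_gradient(params, X, y, h=1e-6):
    """Central-difference oracle for the SSE gradient."""
    theta = params.flatten()
    grad = np.empty_like(theta)
    for k in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        rp = forward(params.with_flat(tp), X) - y
        rm = forward(params.with_flat(tm), X) - y
        grad[k] = (rp @ rp - rm @ rm) / (2 * h)
    return grad


class TestForward:
    def test_zero_weights_give_zero_output(self):
        p = MLPParams(np.zeros((3, 5)), np.zeros(3), np.zeros(3), 0.0)
        x = np.arange(5.0)
        assert forward(p, x)[0] == 0.0

    def test_logsig_at_zero_is_half(self):
        assert logsig(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_hand_evaluated_single_unit(self):
        # 1 hidden unit, w1 = e1, b1 = 0, w2 = 2, b2 = 0, x = e1:
        # output = 2 * logsig(1) = 2 / (1 + e^-1)
        p = MLPParams(np.array([[1.0, 0.0, 0.0]]), np.zeros(1), np.array([2.0]), 0.0)
        out = forward(p, np.array([1.0, 0.0, 0.0]))[0]
        assert out == pytest.approx(2.0 / (1.0 + np.exp(-1.0)), abs=1e-12)
        assert out == pytest.approx(1.4621171572600098, abs=1e-10)

    def test_dimension_mismatch(self):
        p = init_mlp(4, seed=0, n_inputs=13)
        with pytest.raises(ValueError):
            forward(p, np.zeros(7))


class TestInit:
    def test_preset_shapes(self):
        p = init_mlp(26, seed=1)
        assert p.W1.shape == (26, 13) and p.w2.shape == (26,)

    def test_seed_determinism(self):
        a, b = init_mlp(5, seed=7), init_mlp(5, seed=7)
        np.testing.assert_array_equal(a.flatten(), b.flatten())

    def test_zero_hidden_rejected(self):
        with pytest.raises(ValueError):
            init_mlp(0, seed=0)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_analytic_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        p = init_mlp(3, seed=seed, n_inputs=5)
        X = rng.normal(size=(7, 5))
        y = rng.normal(size=7)
        _, g = sse_and_gradient(p, X, y)
        g_fd = finite_difference_gradient(p, X, y)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-7)

    def test_jacobian_consistent_with_gradient(self, rng):
        # dE/dtheta = 2 J^T r links the two analytic derivations
        p = init_mlp(4, seed=3, n_inputs=6)
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        _, g = sse_and_gradient(p, X, y)
        r, J = residual_jacobian(p, X, y)
        np.testing.assert_allclose(g, 2.0 * J.T @ r, rtol=1e-12, atol=1e-12)


class TestBackprop:
    def test_zero_epochs_leaves_params_unchanged(self, rng):
        p = init_mlp(3, seed=0, n_inputs=4)
        X, y = rng.normal(size=(5, 4)), rng.normal(size=5)
        out, trace = train_backprop(p, X, y, config=MLPTrainConfig(max_epochs=0))
        np.testing.assert_array_equal(out.flatten(), p.flatten())
        assert trace == []

    def test_converges_on_single_sample(self):
        p = init_mlp(2, seed=1, n_inputs=3)
        X = np.array([[0.3, -0.2, 0.5]])
        y = np.array([0.7])
        out, trace = train_backprop(
            p, X, y, config=MLPTrainConfig(learning_rate=0.5, max_epochs=2000)
        )
        r = forward(out, X) - y
        assert float(r @ r) < 1e-6

    def test_empty_training_set_rejected(self):
        p = init_mlp(2, seed=0, n_inputs=3)
        with pytest.raises(ValueError):
            train_backprop(p, np.zeros((0, 3)), np.zeros(0))


class TestLevenbergMarquardt:
    def test_large_damping_step_is_scaled_negative_gradient(self, rng):
        p = init_mlp(3, seed=2, n_inputs=4)
        X, y = rng.normal(size=(6, 4)), rng.normal(size=6)
        r, J = residual_jacobian(p, X, y)
        lam = 1e10
        step = np.linalg.solve(J.T @ J + lam * np.eye(J.shape[1]), -J.T @ r)
        np.testing.assert_allclose(step, -J.T @ r / lam, rtol=1e-5)

    def test_training_loss_nonincreasing_over_accepted_steps(self, rng):
        p = init_mlp(4, seed=5, n_inputs=5)
        X, y = rng.normal(size=(20, 5)), rng.normal(size=20)
        _, trace = train_lm(p, X, y, config=MLPTrainConfig(max_epochs=30))
        losses = [t["train_sse"] for t in trace]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_identity_toy_reaches_linear_least_squares_optimum(self, rng):
        # with identity activations the network spans exactly the linear
        # functions, so LM must reach the SSE of a direct lstsq solve
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.3 + rng.normal(0, 0.1, 30)
        A = np.column_stack([X, np.ones(30)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse_opt = float(((y - A @ coef) ** 2).sum())
        p = init_mlp(3, seed=0, n_inputs=3, activation="identity")
        fitted, _ = train_lm(
            p, X, y, config=MLPTrainConfig(max_epochs=100, lm_lambda0=1e-8)
        )
        r = forward(fitted, X) - y
        assert float(r @ r) == pytest.approx(sse_opt, rel=1e-6)

    def test_early_stopping_returns_best_validation_params(self, rng):
        X, y = rng.normal(size=(40, 4)), rng.normal(size=40)
        Xv, yv = rng.normal(size=(15, 4)), rng.normal(size=15)
        p = init_mlp(6, seed=1, n_inputs=4)
        fitted, trace = train_lm(p, X, y, Xv, yv, MLPTrainConfig(max_epochs=50))
        val_final = float(np.mean((forward(fitted, Xv) - yv) ** 2))
        recorded = [t["val_mse"] for t in trace if not np.isnan(t["val_mse"])]
        assert val_final <= min(recorded) + 1e-12

    def test_seeded_runs_bitwise_reproducible(self, small_table, small_split):
        a = fit_mlp(small_table, small_split, hidden_size=6,
                    config=MLPTrainConfig(max_epochs=20))
        b = fit_mlp(small_table, small_split, hidden_size=6,
                    config=MLPTrainConfig(max_epochs=20))
        np.testing.assert_array_equal(a.params.flatten(), b.params.flatten())


class TestPrediction:
    def test_order_preserving_and_permutation_equivariant(self, small_table,
                                                          small_split, rng):
        model = fit_mlp(small_table, small_split, hidden_size=6,
                        config=MLPTrainConfig(max_epochs=20))
        preds = model.predict(small_table)
        assert preds.shape == (small_table.n,)
        perm = rng.permutation(small_table.n)
        np.testing.assert_allclose(
            model.predict(small_table.subset(perm)), preds[perm], atol=1e-12
        )

    def test_json_round_trip(self, small_table, small_split, tmp_path):
        model = fit_mlp(small_table, small_split, hidden_size=6,
                        config=MLPTrainConfig(max_epochs=10))
        p = tmp_path / "mlp.json"
        model.save(p)
        again = load_model(p)
        np.testing.assert_allclose(
            again.predict(small_table), model.predict(small_table), atol=1e-12
        )
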