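"""One-hidden-layer perceptron regressor, written from scratch.

Architecture follows the study's selected structure: 13 inputs, a logistic
sigmoid ("logsig") hidden layer (26 units in the replication preset) and a
single linear ("purelin") output.  Two trainers are provided:

* :func:`train_lm` — Levenberg–Marquardt on the per-sample residuals,
  the study's training function and the default here.  The damped normal
  equations (JᵀJ + λI)Δ = −Jᵀr interpolate between Gauss–Newton (λ→0)
  and small-step gradient descent (λ→∞); λ shrinks on accepted steps and
  grows on rejected ones, so the training SSE trace is nonincreasing.
* :func:`train_backprop` — plain full-batch gradient descent
  w ← w − γ ∂E/∂w on the sum of squared errors E, kept both as an option
  and as the analytically differentiated reference the gradient tests use.

Both trainers monitor validation MSE and return the parameters of the best
validation epoch (early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .data import FeatureScaler, N_PREDICTORS, SampleTable, Split, encode_features, fit_scaler
from .models import FittedRegressor

__all__ = [
    "MLPParams",
    "MLPTrainConfig",
    "MLPRegressor",
    "init_mlp",
    "logsig",
    "forward",
    "sse_and_gradient",
    "residual_jacobian",
    "train_backprop",
    "train_lm",
    "fit_mlp",
]


def logsig(z: np.ndarray) -> np.ndarray:
    """Logistic sigmoid 1 / (1 + e^-z)."""
    return expit(z)


@dataclass
class MLPParams:
    """Weights of a 13-h-1 network: hidden layer (W1, b1), output (w2, b2)."""

    W1: np.ndarray          # (hidden, n_inputs)
    b1: np.ndarray          # (hidden,)
    w2: np.ndarray          # (hidden,)
    b2: float
    activation: str = "logsig"  # "identity" supported for testing

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.w2.shape != (h,):
            raise ValueError("inconsistent parameter shapes")
        if self.activation not in ("logsig", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not (
            np.isfinite(self.W1).all()
            and np.isfinite(self.b1).all()
            and np.isfinite(self.w2).all()
            and np.isfinite(self.b2)
        ):
            raise ValueError("non-finite parameters")

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_params(self) -> int:
        h, d = self.W1.shape
        return h * d + h + h + 1

    def copy(self) -> "MLPParams":
        return MLPParams(self.W1.copy(), self.b1.copy(), self.w2.copy(), float(self.b2), self.activation)

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    def with_flat(self, theta: np.ndarray) -> "MLPParams":
        h, d = self.W1.shape
        W1 = theta[: h * d].reshape(h, d)
        b1 = theta[h * d : h * d + h]
        w2 = theta[h * d + h : h * d + 2 * h]
        b2 = float(theta[-1])
        return MLPParams(W1, b1, w2, b2, self.activation)

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPParams":
        return cls(
            np.asarray(d["W1"]), np.asarray(d["b1"]), np.asarray(d["w2"]),
            float(d["b2"]), d.get("activation", "logsig"),
        )


@dataclass(frozen=True)
class MLPTrainConfig:
    """Trainer settings shared by the backprop and LM loops.

    learning_rate is the crisp backprop step γ; lm_lambda0 with its
    increase/decrease factors controls the LM damping schedule; patience is
    the number of epochs without validation improvement before stopping.
    """

    learning_rate: float = 0.05
    lm_lambda0: float = 1e-2
    lm_increase: float = 10.0
    lm_decrease: float = 10.0
    lm_lambda_max: float = 1e10
    max_epochs: int = 200
    patience: int = 25
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.lm_lambda0 <= 0:
            raise ValueError("learning_rate and lm_lambda0 must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def init_mlp(hidden_size: int, seed: int, n_inputs: int = N_PREDICTORS,
             activation: str = "logsig") -> MLPParams:
    """Seeded uniform [-0.5, 0.5] initialization of all weights and biases."""
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    rng = np.random.default_rng(seed)
    return MLPParams(
        W1=rng.uniform(-0.5, 0.5, size=(hidden_size, n_inputs)),
        b1=rng.uniform(-0.5, 0.5, size=hidden_size),
        w2=rng.uniform(-0.5, 0.5, size=hidden_size),
        b2=float(rng.uniform(-0.5, 0.5)),
        activation=activation,
    )


def _hidden(params: MLPParams, X: np.ndarray) -> np.ndarray:
    net = X @ params.W1.T + params.b1
    if params.activation == "logsig":
        return logsig(net)
    return net


def forward(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Network output for an (n, d) batch (or a single d-vector)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_inputs:
        raise ValueError(f"expected {params.n_inputs} inputs, got {X.shape[1]}")
    H = _hidden(params, X)
    return H @ params.w2 + params.b2


def sse_and_gradient(params: MLPParams, X: np.ndarray, y: np.ndarray):
    """Sum of squared errors E = Σ(ŷ−y)² and its analytic gradient.

    Gradient is returned flattened in the same order as ``flatten()``;
    derived by standard backpropagation through the logsig hidden layer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    H = _hidden(params, X)
    yhat = H @ params.w2 + params.b2
    r = yhat - y
    E = float(r @ r)

    # output layer
    g_w2 = 2.0 * (r @ H)
    g_b2 = 2.0 * r.sum()
    # hidden layer: delta = 2r * w2 * sigma'(net)
    if params.activation == "logsig":
        sprime = H * (1.0 - H)
    else:
        sprime = np.ones_like(H)
    delta = (2.0 * r)[:, None] * params.w2[None, :] * sprime
    g_W1 = delta.T @ X
    g_b1 = delta.sum(axis=0)
    grad = np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]])
    return E, grad


def residual_jacobian(params: MLPParams, X: np.ndarray, y: np.ndarray):
    """Per-sample residuals r_i = ŷ_i − y_i and Jacobian ∂r_i/∂θ (n × p)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    H = _hidden(params, X)
    yhat = H @ params.w2 + params.b2
    r = yhat - y
    if params.activation == "logsig":
        sprime = H * (1.0 - H)
    else:
        sprime = np.ones_like(H)
    S = params.w2[None, :] * sprime                      # (n, h)
    J_W1 = S[:, :, None] * X[:, None, :]                 # (n, h, d)
    J = np.concatenate(
        [J_W1.reshape(n, -1), S, H, np.ones((n, 1))], axis=1
    )
    return r, J


def _val_mse(params: MLPParams, Xv, yv) -> float:
    if Xv is None or len(Xv) == 0:
        return np.nan
    rv = forward(params, Xv) - yv
    return float(np.mean(rv**2))


def train_backprop(
    params: MLPParams,
    X: np.ndarray,
    y: np.ndarray,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    config: MLPTrainConfig = MLPTrainConfig(),
):
    """Full-batch gradient descent w ← w − γ∂E/∂w with best-epoch selection.

    Returns (best-validation parameters, trace) where the trace records
    training SSE and validation MSE per epoch.  With no validation set the
    final-epoch parameters are returned.
    """
    if len(np.atleast_1d(y)) == 0:
        raise ValueError("empty training set")
    params = params.copy()
    theta = params.flatten()
    trace = []
    best_theta, best_val = theta.copy(), _val_mse(params, X_val, y_val)
    for epoch in range(config.max_epochs):
        E, grad = sse_and_gradient(params.with_flat(theta), X, y)
        if not np.isfinite(E):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        theta = theta - config.learning_rate * grad
        cur = params.with_flat(theta)
        vmse = _val_mse(cur, X_val, y_val)
        trace.append({"epoch": epoch, "train_sse": E, "val_mse": vmse})
        if np.isnan(best_val) or (not np.isnan(vmse) and vmse < best_val):
            best_val, best_theta = vmse, theta.copy()
    final = theta if X_val is None else best_theta
    return params.with_flat(final), trace


def train_lm(
    params: MLPParams,
    X: np.ndarray,
    y: np.ndarray,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    config: MLPTrainConfig = MLPTrainConfig(),
):
    """Levenberg–Marquardt least-squares training with early stopping.

    Each epoch solves (JᵀJ + λI)Δ = −Jᵀr; a step is accepted only if it
    lowers the training SSE (so the accepted-loss trace is nonincreasing),
    with λ divided by ``lm_decrease`` on success and multiplied by
    ``lm_increase`` on rejection.  Stops at max_epochs, when λ overflows
    ``lm_lambda_max``, or after ``patience`` epochs without validation
    improvement; the best-validation parameters are returned.
    """
    if len(np.atleast_1d(y)) == 0:
        raise ValueError("empty training set")
    params = params.copy()
    lam = config.lm_lambda0
    r, J = residual_jacobian(params, X, y)
    sse = float(r @ r)
    best = params.copy()
    best_val = _val_mse(params, X_val, y_val)
    stall = 0
    trace = [{"epoch": -1, "train_sse": sse, "val_mse": best_val, "lambda": lam}]

    for epoch in range(config.max_epochs):
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        while lam <= config.lm_lambda_max:
            A = JtJ + lam * np.eye(JtJ.shape[0])
            try:
                step = np.linalg.solve(A, -Jtr)
            except np.linalg.LinAlgError:
                lam *= config.lm_increase
                continue
            cand = params.with_flat(params.flatten() + step)
            r_new = forward(cand, X) - y
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                params, sse = cand, sse_new
                lam = max(lam / config.lm_decrease, 1e-15)
                accepted = True
                break
            lam *= config.lm_increase
        if not accepted:
            break  # damping overflow: converged as far as LM can go
        r, J = residual_jacobian(params, X, y)
        vmse = _val_mse(params, X_val, y_val)
        trace.append({"epoch": epoch, "train_sse": sse, "val_mse": vmse, "lambda": lam})
        if np.isnan(best_val) or (not np.isnan(vmse) and vmse < best_val - config.tol):
            best_val, best, stall = vmse, params.copy(), 0
        else:
            stall += 1
            if X_val is not None and stall >= config.patience:
                break
        if sse < config.tol:
            break
    final = params if X_val is None else best
    return final, trace


class MLPRegressor(FittedRegressor):
    """Trained perceptron plus its feature/target scaler."""

    model_type = "mlp"

    def __init__(self, params: MLPParams, scaler: FeatureScaler,
                 trace: Optional[list] = None, seed: Optional[int] = None):
        super().__init__(scaler)
        self.params = params
        self.trace = trace or []
        self.seed = seed

    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return forward(self.params, Xs)

    def _params_dict(self) -> dict:
        return {"mlp": self.params.to_dict(), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "MLPRegressor":
        return cls(
            MLPParams.from_dict(d["params"]["mlp"]),
            FeatureScaler.from_dict(d["scaler"]),
            seed=d["params"].get("seed"),
        )


def fit_mlp(
    table: SampleTable,
    split: Split,
    hidden_size: int = 26,
    trainer: str = "lm",
    seed: int = 0,
    config: MLPTrainConfig = MLPTrainConfig(),
) -> MLPRegressor:
    """Scale on the training rows, train on scaled data, wrap the result.

    ``trainer`` selects Levenberg–Marquardt ("lm", the replication default)
    or plain backprop gradient descent ("backprop").
    """
    X, y = encode_features(table)
    if y is None:
        raise ValueError("training table must include the hypericin target")
    tr, va = list(split.train_idx), list(split.val_idx)
    scaler = fit_scaler(X[tr], y[tr])
    Xs, ys = scaler.transform(X), scaler.transform_target(y)
    params = init_mlp(hidden_size, seed)
    train = train_lm if trainer == "lm" else train_backprop
    if trainer not in ("lm", "backprop"):
        raise ValueError(f"unknown trainer {trainer!r}")
    fitted, trace = train(params, Xs[tr], ys[tr], Xs[va], ys[va], config)
    return MLPRegressor(fitted, scaler, trace=trace, seed=seed)
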