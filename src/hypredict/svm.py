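"""ε-insensitive support-vector regression with a Gaussian kernel.

The primal trades flatness against tube violations, minimizing
½‖w‖² + C Σξ subject to residuals within the ε-tube; prediction is the
kernel expansion y(x) = Σ β_i K(x_i, x) + b over the support vectors,
with K(x_i, x_j) = exp(−γ‖x_i − x_j‖²).

The convex dual is solved from scratch by an SMO-style maximal-violating-
pair solver over the 2n box-constrained variables (α⁺, α⁻) with the single
equality constraint Σ(α⁺ − α⁻) = 0, the same working-set scheme classical
SVM libraries use.  Signed coefficients β = α⁺ − α⁻ obey |β_i| ≤ C and
Σβ_i = 0 at the solution; samples with residuals strictly inside the tube
end with β_i = 0 (KKT).

Replication preset: ε = 0.0002 and C = 995.2 on the [-1, 1]-scaled target;
γ defaults to 1/13 (one over the feature count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .data import (
    FeatureScaler,
    N_PREDICTORS,
    SampleTable,
    Split,
    encode_features,
    fit_scaler,
)
from .models import FittedRegressor

__all__ = [
    "SVRConfig",
    "SVRParams",
    "SVRRegressor",
    "gaussian_kernel",
    "kernel_matrix",
    "dual_objective",
    "fit_svr",
]


def gaussian_kernel(x_i: np.ndarray, x_j: np.ndarray, gamma: float) -> float:
    """K(x_i, x_j) = exp(−γ‖x_i − x_j‖²); 1 iff the points coincide."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    d2 = float(((np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)) ** 2).sum())
    return float(np.exp(-gamma * d2))


def kernel_matrix(X: np.ndarray, Z: Optional[np.ndarray] = None, gamma: float = 1.0) -> np.ndarray:
    Z = X if Z is None else Z
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Z), "sqeuclidean")
    return np.exp(-gamma * d2)


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameters: C (tube-violation cost), ε (tube half-width),
    γ (kernel width), solver KKT tolerance and iteration cap."""

    C: float = 995.2
    epsilon: float = 0.0002
    gamma: float = 1.0 / N_PREDICTORS
    tol: float = 1e-8
    max_iter: int = 200_000
    sv_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class SVRParams:
    """Signed dual coefficients β = α⁺ − α⁻ on the support vectors, bias b."""

    beta: np.ndarray            # (n_sv,) signed dual coefficients
    support_vectors: np.ndarray  # (n_sv, d)
    bias: float
    config: SVRConfig

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.support_vectors = np.atleast_2d(np.asarray(self.support_vectors, dtype=float))

    @property
    def n_sv(self) -> int:
        return len(self.beta)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "bias": self.bias,
            "config": {
                "C": self.config.C,
                "epsilon": self.config.epsilon,
                "gamma": self.config.gamma,
                "tol": self.config.tol,
                "max_iter": self.config.max_iter,
                "sv_tol": self.config.sv_tol,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRParams":
        return cls(
            np.asarray(d["beta"]),
            np.asarray(d["support_vectors"]),
            float(d["bias"]),
            SVRConfig(**d["config"]),
        )


def evaluate(params: SVRParams, X: np.ndarray) -> np.ndarray:
    """Kernel expansion Σ β_i K(x_i, x) + b (constant b with no SVs)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if params.n_sv == 0:
        return np.full(X.shape[0], params.bias)
    Kx = kernel_matrix(X, params.support_vectors, params.config.gamma)
    # row-wise reduction keeps duplicate input rows bit-identical
    return (Kx * params.beta).sum(axis=1) + params.bias


def dual_objective(K: np.ndarray, y: np.ndarray, beta: np.ndarray, epsilon: float) -> float:
    """½βᵀKβ − yᵀβ + ε‖β‖₁ — the (negated-maximization) dual objective."""
    beta = np.asarray(beta, dtype=float)
    return float(0.5 * beta @ K @ beta - y @ beta + epsilon * np.abs(beta).sum())


class SolverError(RuntimeError):
    pass


def _smo(K: np.ndarray, y: np.ndarray, config: SVRConfig):
    """Maximal-violating-pair SMO over (α⁺, α⁻) ∈ [0, C]^{2n}, Σβ = 0.

    Returns (beta, n_iter, final KKT gap)."""
    n = len(y)
    C, eps, tol = config.C, config.epsilon, config.tol
    a_pos = np.zeros(n)
    a_neg = np.zeros(n)
    Kbeta = np.zeros(n)
    tau = 1e-12

    diagK = np.diag(K).copy()

    for it in range(config.max_iter):
        if it and it % 10_000 == 0:
            Kbeta = K @ (a_pos - a_neg)  # flush incremental rounding drift
        g_pos = Kbeta + eps - y        # gradient wrt α⁺
        g_neg = -Kbeta + eps + y       # gradient wrt α⁻

        # -s_k G_k for every 2n variable; s=+1 on the plus block
        f_pos = -g_pos
        f_neg = g_neg
        up_pos = a_pos < C - tau
        up_neg = a_neg > tau
        down_pos = a_pos > tau
        down_neg = a_neg < C - tau

        cand_up = np.concatenate([np.where(up_pos, f_pos, -np.inf),
                                  np.where(up_neg, f_neg, -np.inf)])
        cand_dn = np.concatenate([np.where(down_pos, f_pos, np.inf),
                                  np.where(down_neg, f_neg, np.inf)])
        i = int(np.argmax(cand_up))
        gap = cand_up[i] - np.min(cand_dn)
        if gap < tol:
            return a_pos - a_neg, it, float(gap)

        # second-order working-set selection: among down-eligible partners
        # that violate with i, maximize b^2 / a (the one-pair objective gain)
        si_sel = 1 if i < n else -1
        ii_sel = i if i < n else i - n
        k_row = K[ii_sel]
        quad_pos = diagK[ii_sel] + diagK - 2.0 * si_sel * k_row   # vs plus block
        quad_neg = diagK[ii_sel] + diagK + 2.0 * si_sel * k_row   # vs minus block
        quad_all = np.concatenate([np.maximum(quad_pos, tau),
                                   np.maximum(quad_neg, tau)])
        b_vec = cand_up[i] - cand_dn
        with np.errstate(invalid="ignore"):
            gain = np.where(b_vec > tol, b_vec**2 / quad_all, -np.inf)
        j = int(np.argmax(gain))

        si, ii = (1, i) if i < n else (-1, i - n)
        sj, jj = (1, j) if j < n else (-1, j - n)
        Gi = g_pos[ii] if si == 1 else g_neg[ii]
        Gj = g_pos[jj] if sj == 1 else g_neg[jj]
        ai = a_pos[ii] if si == 1 else a_neg[ii]
        aj = a_pos[jj] if sj == 1 else a_neg[jj]
        Kii, Kjj, Kij = K[ii, ii], K[jj, jj], K[ii, jj]

        if si != sj:
            quad = max(Kii + Kjj + 2.0 * Kij, tau)
            delta = (-Gi - Gj) / quad
            diff = ai - aj
            ai, aj = ai + delta, aj + delta
            if diff > 0:
                if aj < 0:
                    aj, ai = 0.0, diff
            else:
                if ai < 0:
                    ai, aj = 0.0, -diff
            if diff > 0:
                if ai > C:
                    ai, aj = C, C - diff
            else:
                if aj > C:
                    aj, ai = C, C + diff
        else:
            quad = max(Kii + Kjj - 2.0 * Kij, tau)
            delta = (Gi - Gj) / quad
            ssum = ai + aj
            ai, aj = ai - delta, aj + delta
            if ssum > C:
                if ai > C:
                    ai, aj = C, ssum - C
            else:
                if aj < 0:
                    aj, ai = 0.0, ssum
            if ssum > C:
                if aj > C:
                    aj, ai = C, ssum - C
            else:
                if ai < 0:
                    ai, aj = 0.0, ssum
        ai = min(max(ai, 0.0), C)
        aj = min(max(aj, 0.0), C)

        old_i = a_pos[ii] if si == 1 else a_neg[ii]
        old_j = a_pos[jj] if sj == 1 else a_neg[jj]
        if si == 1:
            a_pos[ii] = ai
        else:
            a_neg[ii] = ai
        if sj == 1:
            a_pos[jj] = aj
        else:
            a_neg[jj] = aj
        dbeta_i = si * (ai - old_i)
        dbeta_j = sj * (aj - old_j)
        Kbeta += K[:, ii] * dbeta_i + K[:, jj] * dbeta_j

    raise SolverError(
        f"SMO did not reach KKT tolerance {tol} within {config.max_iter} "
        f"iterations (last gap {gap:.3e})"
    )


def _bias(K: np.ndarray, y: np.ndarray, beta: np.ndarray, config: SVRConfig) -> float:
    """Bias from margin-interior support vectors, averaged; KKT-interval
    midpoint when no coefficient is strictly inside the box."""
    C, eps = config.C, config.epsilon
    Kbeta = K @ beta
    free_tol = max(1e-8 * C, 1e-12)
    bs = []
    for i in range(len(y)):
        if free_tol < beta[i] < C - free_tol:       # α⁺ free: y − Kβ − ε
            bs.append(y[i] - Kbeta[i] - eps)
        elif -C + free_tol < beta[i] < -free_tol:   # α⁻ free: y − Kβ + ε
            bs.append(y[i] - Kbeta[i] + eps)
    if bs:
        return float(np.mean(bs))
    # fallback: midpoint of the feasible interval from the bound KKT conditions
    lo, hi = -np.inf, np.inf
    for i in range(len(y)):
        up = y[i] - Kbeta[i] - eps   # from α⁺ side
        dn = y[i] - Kbeta[i] + eps   # from α⁻ side
        if beta[i] < C - free_tol:
            hi = min(hi, dn)
        if beta[i] > -C + free_tol:
            lo = max(lo, up)
    if not np.isfinite(lo) or not np.isfinite(hi):
        return float(np.mean(y - Kbeta))
    return float((lo + hi) / 2.0)


def fit_svr(X: np.ndarray, y: np.ndarray, config: SVRConfig = SVRConfig()) -> SVRParams:
    """Solve the ε-SVR dual on (scaled) training data to KKT tolerance.

    Only samples with |β_i| above ``config.sv_tol`` are retained as support
    vectors; the bias is averaged over margin-interior support vectors.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 training samples")
    K = kernel_matrix(X, gamma=config.gamma)
    beta, _, _ = _smo(K, y, config)
    b = _bias(K, y, beta, config)
    sv = np.abs(beta) > config.sv_tol
    return SVRParams(beta[sv], X[sv], b, config)


class SVRRegressor(FittedRegressor):
    """Trained ε-SVR plus its feature/target scaler."""

    model_type = "svr"

    def __init__(self, params: SVRParams, scaler: FeatureScaler,
                 seed: Optional[int] = None):
        super().__init__(scaler)
        self.params = params
        self.seed = seed

    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return evaluate(self.params, Xs)

    def _params_dict(self) -> dict:
        return {"svr": self.params.to_dict(), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SVRRegressor":
        return cls(
            SVRParams.from_dict(d["params"]["svr"]),
            FeatureScaler.from_dict(d["scaler"]),
            seed=d["params"].get("seed"),
        )


def fit_svr_model(
    table: SampleTable,
    split: Split,
    config: SVRConfig = SVRConfig(),
    seed: int = 0,
) -> SVRRegressor:
    """Scale on training rows, solve the dual in scaled space, wrap it.

    ε and C act on the [-1, 1]-scaled target; the validation partition is
    untouched (ε-SVR has no epoch structure to early-stop)."""
    X, y = encode_features(table)
    if y is None:
        raise ValueError("training table must include the hypericin target")
    tr = list(split.train_idx)
    scaler = fit_scaler(X[tr], y[tr])
    Xs, ys = scaler.transform(X), scaler.transform_target(y)
    params = fit_svr(Xs[tr], ys[tr], config)
    return SVRRegressor(params, scaler, seed=seed)
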