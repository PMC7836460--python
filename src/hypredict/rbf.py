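"""Gaussian radial-basis-function network regressor.

Hidden units are Gaussian bumps exp(−‖x − a_j‖² / (2σ²)) centred on
selected training points with one shared spread σ; the output is a linear
combination Σ w_j R_j(x) + b whose weights and bias are refit by ordinary
least squares each time a neuron is added.  Centres are chosen by greedy
forward selection — at each step the candidate training point whose
inclusion most reduces training SSE joins the network — mirroring the
incremental neuron addition of classic RBF toolboxes.  The replication
preset is 48 neurons with spread 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .data import FeatureScaler, SampleTable, Split, encode_features, fit_scaler
from .models import FittedRegressor

__all__ = [
    "RBFParams",
    "RBFRegressor",
    "rbf_activation",
    "design_matrix",
    "fit_rbf",
]


def rbf_activation(x: np.ndarray, center: np.ndarray, spread: float) -> np.ndarray:
    """Gaussian basis exp(−‖x − a‖² / (2σ²)) ∈ (0, 1]; symmetric in (x, a)."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    center = np.asarray(center, dtype=float).ravel()
    d2 = ((x - center) ** 2).sum(axis=1)
    out = np.exp(-d2 / (2.0 * spread**2))
    return out if out.size > 1 else float(out[0])


def design_matrix(X: np.ndarray, centers: np.ndarray, spread: float) -> np.ndarray:
    """(n, m) matrix of Gaussian activations of every sample at every centre."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(centers), "sqeuclidean")
    return np.exp(-d2 / (2.0 * spread**2))


@dataclass
class RBFParams:
    """Centres, shared spread, output weights and bias of a fitted network."""

    centers: np.ndarray      # (m, d)
    spread: float
    weights: np.ndarray      # (m,)
    bias: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centers.shape[0] < 1:
            raise ValueError("need at least one neuron")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.weights.shape != (self.centers.shape[0],):
            raise ValueError("one output weight per centre required")

    @property
    def m(self) -> int:
        return self.centers.shape[0]

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "spread": self.spread,
            "weights": self.weights.tolist(),
            "bias": self.bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFParams":
        return cls(
            np.asarray(d["centers"]), float(d["spread"]),
            np.asarray(d["weights"]), float(d["bias"]),
        )


def evaluate(params: RBFParams, X: np.ndarray) -> np.ndarray:
    """Network output y = Σ_j w_j R_j(x) + b for a batch.

    Summed row by row (not BLAS matvec) so duplicate input rows yield
    bit-identical predictions."""
    Phi = design_matrix(X, params.centers, params.spread)
    return (Phi * params.weights).sum(axis=1) + params.bias


_RIDGE = 1e-10  # stabilizer engaged only when the plain solve is rank-deficient


def _ols(Phi: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares output weights + bias; ridge-stabilized if degenerate.

    Returns (weights, bias, sse)."""
    n, m = Phi.shape
    A = np.column_stack([Phi, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < min(n, m + 1):  # m + 1 > n is merely underdetermined, not degenerate
        warnings.warn(
            "rank-deficient RBF design; using ridge-stabilized solve",
            RuntimeWarning,
            stacklevel=3,
        )
        coef = np.linalg.solve(A.T @ A + _RIDGE * np.eye(m + 1), A.T @ y)
    resid = y - A @ coef
    return coef[:m], float(coef[m]), float(resid @ resid)


def fit_rbf(
    X: np.ndarray,
    y: np.ndarray,
    max_neurons: int = 48,
    spread: float = 50.0,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    patience: int = 10,
    strategy: str = "greedy",
    seed: int = 0,
) -> RBFParams:
    """Fit centres and output weights on (scaled) training data.

    ``strategy="greedy"`` (default) grows the network one training point at
    a time, always taking the candidate centre that most reduces training
    SSE, refitting the output layer by least squares after each addition,
    and keeping the configuration with the best validation MSE (training
    SSE if no validation set is given).  ``strategy="kmeans"`` instead
    places ``max_neurons`` centres by a small seeded k-means and fits the
    output layer once.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not 1 <= max_neurons <= n:
        raise ValueError("need 1 <= max_neurons <= n_train")

    if strategy == "kmeans":
        centers = _kmeans_centers(X, max_neurons, seed)
        Phi = design_matrix(X, centers, spread)
        w, b, _ = _ols(Phi, y)
        return RBFParams(centers, spread, w, b)
    if strategy != "greedy":
        raise ValueError(f"unknown strategy {strategy!r}")

    Phi_full = design_matrix(X, X, spread)   # candidate activations
    chosen: list[int] = []
    best_result = None
    best_score = np.inf
    stall = 0
    last_sse = np.inf

    for _ in range(max_neurons):
        best_cand, best_cand_sse, best_fit = None, np.inf, None
        for c in range(n):
            if c in chosen:
                continue
            cols = chosen + [c]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                w, b, sse = _ols(Phi_full[:, cols], y)
            if sse < best_cand_sse:
                best_cand, best_cand_sse, best_fit = c, sse, (w, b)
        if best_cand is None:
            break
        chosen.append(best_cand)
        # refit once outside the suppressed block so a real degeneracy warns
        w, b, sse = _ols(Phi_full[:, chosen], y)
        last_sse = min(sse, last_sse)
        params = RBFParams(X[chosen], spread, w, b)
        if X_val is not None and len(X_val) > 0:
            rv = evaluate(params, X_val) - y_val
            score = float(np.mean(rv**2))
        else:
            score = sse
        if score < best_score - 1e-15:
            best_score, best_result, stall = score, params, 0
        else:
            stall += 1
            if X_val is not None and stall >= patience:
                break
    if best_result is None:  # pragma: no cover - max_neurons >= 1 guarantees a fit
        raise RuntimeError("greedy selection produced no model")
    return best_result


def _kmeans_centers(X: np.ndarray, k: int, seed: int, iters: int = 50) -> np.ndarray:
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(len(X), size=k, replace=False)].copy()
    for _ in range(iters):
        d2 = cdist(X, centers, "sqeuclidean")
        lab = d2.argmin(axis=1)
        new = centers.copy()
        for j in range(k):
            pts = X[lab == j]
            if len(pts):
                new[j] = pts.mean(axis=0)
        if np.allclose(new, centers):
            break
        centers = new
    return centers


class RBFRegressor(FittedRegressor):
    """Trained RBF network plus its feature/target scaler."""

    model_type = "rbf"

    def __init__(self, params: RBFParams, scaler: FeatureScaler,
                 seed: Optional[int] = None):
        super().__init__(scaler)
        self.params = params
        self.seed = seed

    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return evaluate(self.params, Xs)

    def _params_dict(self) -> dict:
        return {"rbf": self.params.to_dict(), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "RBFRegressor":
        return cls(
            RBFParams.from_dict(d["params"]["rbf"]),
            FeatureScaler.from_dict(d["scaler"]),
            seed=d["params"].get("seed"),
        )


def fit_rbf_model(
    table: SampleTable,
    split: Split,
    max_neurons: int = 48,
    spread: float = 50.0,
    strategy: str = "greedy",
    seed: int = 0,
) -> RBFRegressor:
    """Scale on training rows, fit the network in scaled space, wrap it."""
    X, y = encode_features(table)
    if y is None:
        raise ValueError("training table must include the hypericin target")
    tr, va = list(split.train_idx), list(split.val_idx)
    scaler = fit_scaler(X[tr], y[tr])
    Xs, ys = scaler.transform(X), scaler.transform_target(y)
    params = fit_rbf(
        Xs[tr], ys[tr], max_neurons=min(max_neurons, len(tr)), spread=spread,
        X_val=Xs[va], y_val=ys[va], strategy=strategy, seed=seed,
    )
    return RBFRegressor(params, scaler, seed=seed)
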