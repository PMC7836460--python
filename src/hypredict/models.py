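"""Shared regressor surface: scaled-space prediction plus JSON persistence.

Every fitted model (MLP, RBF network, epsilon-SVR) carries the min-max
scaler fitted on its training rows; `predict` takes raw-unit samples,
scales them, runs the model in scaled space and returns hypericin in mg/g.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import FeatureScaler, N_PREDICTORS, SampleTable, encode_features

__all__ = ["FittedRegressor", "load_model"]


class FittedRegressor:
    """Base class for the three trained regressors."""

    model_type: str = "base"

    def __init__(self, scaler: FeatureScaler):
        self.scaler = scaler

    # subclasses implement prediction on scaled features
    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict hypericin (mg/g) from a raw-unit (n, 13) design matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_PREDICTORS:
            raise ValueError(
                f"expected {N_PREDICTORS} predictor columns, got {X.shape[1]}"
            )
        Xs = self.scaler.transform(X)
        ys = self.predict_scaled(Xs)
        return self.scaler.inverse_transform_target(ys)

    def predict(self, table: SampleTable) -> np.ndarray:
        X, _ = encode_features(table)
        return self.predict_matrix(X)

    # --- persistence -----------------------------------------------------
    def _params_dict(self) -> dict:  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:
        return {
            "model_type": self.model_type,
            "scaler": self.scaler.to_dict(),
            "params": self._params_dict(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRegressor":  # pragma: no cover
        raise NotImplementedError


def load_model(path) -> FittedRegressor:
    """Load any saved regressor, dispatching on its recorded model type."""
    from . import mlp, rbf, svm

    d = json.loads(Path(path).read_text())
    registry = {
        "mlp": mlp.MLPRegressor,
        "rbf": rbf.RBFRegressor,
        "svr": svm.SVRRegressor,
    }
    try:
        cls = registry[d["model_type"]]
    except KeyError:
        raise ValueError(f"unknown model type {d.get('model_type')!r}") from None
    return cls.from_dict(d)
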