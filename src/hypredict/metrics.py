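"""Accuracy metrics, per-partition evaluation and model selection.

Metrics are always computed on the original mg/g scale: MSE, RMSE, MAE,
and two flavours of R².  ``r2_ratio`` is the regression-SS over total-SS
form Σ(ŷ−ȳ)² / Σ(y−ȳ)² (with ȳ the mean of the observed targets in the
evaluated partition), which the study uses for model comparison; unlike
the conventional 1 − SSE/SST (``r2``) it is nonnegative and can exceed 1
for biased predictors, so both are reported side by side.

Model selection ranks candidates by test-partition ``r2_ratio`` (highest
wins), breaking ties by lower test RMSE and then lexicographic model id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SampleTable, Split, encode_features
from .models import FittedRegressor

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "evaluate_model",
    "select_best",
    "METRIC_NAMES",
]

METRIC_NAMES = ("mse", "rmse", "mae", "r2_ratio", "r2")
PARTITIONS = ("train", "val", "test")


def compute_metrics(targets: np.ndarray, predictions: np.ndarray) -> dict[str, float]:
    """MSE, RMSE (=√MSE), MAE and both R² forms for one partition."""
    y = np.asarray(targets, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("targets and predictions must be equal-length vectors")
    if len(y) < 2:
        raise ValueError("need at least 2 samples per partition")
    err = y - yhat
    mse = float(np.mean(err**2))
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: zero target variance")
    ssr = float(np.sum((yhat - ybar) ** 2))
    sse = float(np.sum(err**2))
    return {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mae": float(np.mean(np.abs(err))),
        "r2_ratio": ssr / sst,
        "r2": 1.0 - sse / sst,
    }


@dataclass
class MetricsReport:
    """Per-partition metric table for one model."""

    model_id: str
    table: pd.DataFrame  # index: partition; columns: METRIC_NAMES + n

    def metric(self, partition: str, name: str) -> float:
        return float(self.table.loc[partition, name])

    def to_dict(self) -> dict:
        return {"model_id": self.model_id, "metrics": self.table.to_dict(orient="index")}


def evaluate_model(
    model: FittedRegressor,
    split: Split,
    table: SampleTable,
    model_id: str | None = None,
) -> MetricsReport:
    """Metrics on train/validation/test partitions, in mg/g.

    The model must already be trained; the test rows are only ever touched
    here, after training and selection decisions."""
    X, y = encode_features(table)
    if y is None:
        raise ValueError("evaluation table must include the hypericin target")
    preds = model.predict_matrix(X)
    rows = {}
    for part, idx in zip(
        PARTITIONS, (split.train_idx, split.val_idx, split.test_idx)
    ):
        idx = list(idx)
        if not idx:
            raise ValueError(f"empty {part} partition")
        rows[part] = {**compute_metrics(y[idx], preds[idx]), "n": len(idx)}
    return MetricsReport(
        model_id=model_id or model.model_type,
        table=pd.DataFrame.from_dict(rows, orient="index").loc[list(PARTITIONS)],
    )


def select_best(reports: list[MetricsReport]) -> tuple[str, pd.DataFrame]:
    """Pick the winning model and emit the comparison table.

    Ranking key: highest test ``r2_ratio``; ties by lower test RMSE, then
    model id.  The returned table has one row per (model, partition).
    """
    if not reports:
        raise ValueError("no reports to select from")
    ranked = sorted(
        reports,
        key=lambda r: (-r.metric("test", "r2_ratio"), r.metric("test", "rmse"), r.model_id),
    )
    frames = []
    for rep in reports:
        df = rep.table.copy()
        df.insert(0, "model", rep.model_id)
        df.insert(1, "partition", df.index)
        frames.append(df.reset_index(drop=True))
    comparison = pd.concat(frames, ignore_index=True)
    comparison["selected"] = comparison["model"] == ranked[0].model_id
    return ranked[0].model_id, comparison
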