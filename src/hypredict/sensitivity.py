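"""One-at-a-time sensitivity analysis of a trained regressor.

For each of the 13 predictors a perturbation grid is built: the variable
of interest sweeps mean ± (width × SD) — clipped to the observed bounds —
while every other variable is pinned at its mean (rounded to the nearest
valid code for ordinals).  The model predicts along the grid and the
population SD of those predictions is the variable's raw sensitivity in
mg/g; dividing by the largest raw SD normalizes the scores onto [0, 1],
so the most influential variable scores exactly 1.  Response curves for
each variable (the grid and its predictions, with a monotonicity summary)
reproduce the partial-trend view the study uses to interpret the drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DEFAULT_SCHEMA, PREDICTOR_NAMES, SampleTable, VariableSchema
from .models import FittedRegressor

__all__ = [
    "SampleStats",
    "SensitivityReport",
    "build_perturbation_grid",
    "sensitivity_scores",
    "response_curve",
]


@dataclass(frozen=True)
class SampleStats:
    """Per-variable mean/SD (continuous) and code set (ordinal), computed
    from the training table the model was fitted on."""

    means: dict[str, float]
    sds: dict[str, float]
    n: int
    schema: tuple[VariableSchema, ...] = DEFAULT_SCHEMA

    @classmethod
    def from_table(cls, table: SampleTable) -> "SampleStats":
        means, sds = {}, {}
        for name in PREDICTOR_NAMES:
            col = table.data[name].to_numpy(dtype=float)
            means[name] = float(col.mean())
            sds[name] = float(col.std(ddof=1))
        return cls(means=means, sds=sds, n=table.n, schema=table.schema)

    def variable(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(f"unknown variable {name!r}")

    def baseline_value(self, name: str) -> float:
        """Fixed value for a non-swept variable: its mean, rounded to the
        nearest valid code for ordinals."""
        var = self.variable(name)
        if var.kind == "ordinal":
            codes = np.asarray(var.code_values)
            return float(codes[np.argmin(np.abs(codes - self.means[name]))])
        return self.means[name]


@dataclass
class SensitivityReport:
    """Raw (mg/g) and normalized [0, 1] sensitivity per variable."""

    model_id: str
    table: pd.DataFrame  # columns: raw_sd, score, rank; index: variable
    grid_size: int

    def top(self, k: int) -> list[str]:
        return list(self.table.sort_values("rank").index[:k])


def build_perturbation_grid(
    variable: str,
    stats: SampleStats,
    k: int = 21,
    width: float = 1.0,
) -> SampleTable:
    """Grid table sweeping one variable with all others fixed at baseline.

    Continuous: k evenly spaced values over mean ± width·SD, clipped to the
    schema bounds.  Ordinal: every valid code.
    """
    if k < 3:
        raise ValueError("grid size k must be >= 3")
    var = stats.variable(variable)  # raises KeyError for unknown names
    if var.kind == "ordinal":
        values = np.asarray(var.code_values, dtype=float)
    else:
        lo = max(stats.means[variable] - width * stats.sds[variable], var.bounds[0])
        hi = min(stats.means[variable] + width * stats.sds[variable], var.bounds[1])
        values = np.linspace(lo, hi, k)
    cols = {}
    for name in PREDICTOR_NAMES:
        if name == variable:
            cols[name] = values
        else:
            cols[name] = np.full(len(values), stats.baseline_value(name))
    return SampleTable(pd.DataFrame(cols))


def sensitivity_scores(
    model: FittedRegressor,
    stats: SampleStats,
    k: int = 21,
    width: float = 1.0,
    model_id: str | None = None,
) -> SensitivityReport:
    """Raw output SD per variable plus scores normalized by the maximum.

    If every raw SD is zero (a constant model) the scores are defined as 0
    and a warning is emitted.
    """
    raw = {}
    for name in PREDICTOR_NAMES:
        grid = build_perturbation_grid(name, stats, k=k, width=width)
        preds = model.predict(grid)
        raw[name] = float(np.std(preds))  # population SD over the grid
    max_raw = max(raw.values())
    if max_raw == 0.0:
        warnings.warn("all raw sensitivities are zero; scores set to 0", RuntimeWarning)
        scores = {name: 0.0 for name in raw}
    else:
        scores = {name: v / max_raw for name, v in raw.items()}
    df = pd.DataFrame(
        {"raw_sd": pd.Series(raw), "score": pd.Series(scores)}
    )
    df["rank"] = df["raw_sd"].rank(ascending=False, method="first").astype(int)
    df.index.name = "variable"
    return SensitivityReport(
        model_id=model_id or model.model_type, table=df, grid_size=k
    )


def _monotonicity(values: np.ndarray, preds: np.ndarray, atol: float = 1e-12) -> str:
    d = np.diff(preds[np.argsort(values)])
    if np.all(np.abs(d) <= atol):
        return "flat"
    if np.all(d >= -atol):
        return "increasing"
    if np.all(d <= atol):
        return "decreasing"
    return "mixed"


def response_curve(
    model: FittedRegressor,
    variable: str,
    stats: SampleStats,
    k: int = 21,
    width: float = 1.0,
) -> tuple[pd.DataFrame, str]:
    """(value, prediction) series along the variable's grid, plus a
    monotonicity tag ("increasing" / "decreasing" / "flat" / "mixed")."""
    grid = build_perturbation_grid(variable, stats, k=k, width=width)
    values = grid.data[variable].to_numpy(dtype=float)
    preds = model.predict(grid)
    curve = pd.DataFrame({variable: values, "prediction": preds})
    return curve, _monotonicity(values, preds)
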