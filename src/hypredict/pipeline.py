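"""Config-driven end-to-end runner and the new-sample prediction endpoint.

A run executes, in order: data loading (or synthetic generation) →
train/validation/test split → training of the three regressors (MLP, RBF
network, ε-SVR) → per-partition evaluation and selection of the best model
by test R² → one-at-a-time sensitivity analysis of the selected model →
artifact export.  Every artifact directory contains the resolved config
snapshot (with its hash) and all seeds, and a rerun from the same snapshot
reproduces every CSV byte for byte.

``predict_new`` is the text-mode stand-in for the original point-and-click
front end: it takes any saved model and a CSV of habitat descriptors and
appends predicted hypericin (mg/g), warning — not failing — when inputs
fall outside the training range, where the model is extrapolating beyond
the conditions it was calibrated for.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data import (
    PREDICTOR_NAMES,
    SampleTable,
    Split,
    TARGET_NAME,
    encode_features,
    load_samples,
    save_samples,
    split_dataset,
)
from .metrics import MetricsReport, evaluate_model, select_best
from .mlp import MLPTrainConfig, fit_mlp
from .models import FittedRegressor, load_model
from .rbf import fit_rbf_model
from .sensitivity import SampleStats, response_curve, sensitivity_scores
from .svm import SVRConfig, fit_svr_model
from .synth import DEFAULT_CONFIG, generate_dataset

logger = logging.getLogger("hypredict")

__all__ = ["RunConfig", "RunArtifacts", "run_pipeline", "predict_new", "REPLICATION_PRESET"]

_CSV_FLOAT = "%.12g"  # fixed format so reruns are byte-identical


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    data_source: str = "synthetic"   # "synthetic" or a CSV path
    n_samples: int = 100
    data_seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    mlp_hidden: int = 26
    mlp_trainer: str = "lm"
    mlp_epochs: int = 200
    mlp_seed: int = 0
    rbf_neurons: int = 48
    rbf_spread: float = 50.0
    rbf_strategy: str = "greedy"
    svr_c: float = 995.2
    svr_epsilon: float = 0.0002
    svr_gamma: float = 1.0 / 13.0
    sensitivity_k: int = 21
    sensitivity_width: float = 1.0

    def validate(self) -> None:
        fr = self.split_fractions
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise PipelineError("split", f"invalid fractions {fr}")
        if self.mlp_trainer not in ("lm", "backprop"):
            raise PipelineError("train", f"unknown MLP trainer {self.mlp_trainer!r}")
        if self.rbf_strategy not in ("greedy", "kmeans"):
            raise PipelineError("train", f"unknown RBF strategy {self.rbf_strategy!r}")
        if min(self.svr_c, self.svr_gamma) <= 0 or self.svr_epsilon < 0:
            raise PipelineError("train", "invalid SVR hyperparameters")
        if self.sensitivity_k < 3:
            raise PipelineError("sensitivity", "grid size must be >= 3")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise PipelineError("config", "config file must contain a mapping")
        known = set(cls().to_dict())
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# Hyperparameters as printed in the study: MLP 13-26-1 (logsig/purelin, LM),
# RBF 48 neurons spread 50, SVR epsilon 0.0002 C 995.2; n = 100 samples
# split 60/20/20.
REPLICATION_PRESET = RunConfig()


@dataclass
class RunArtifacts:
    """Paths and in-memory results of a completed run."""

    outdir: Path
    config: RunConfig
    selected_model: str
    model_paths: dict[str, Path]
    reports: dict[str, MetricsReport]
    comparison: pd.DataFrame
    sensitivity: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def _train_all(config: RunConfig, table: SampleTable, split: Split,
               collected: list[str]) -> dict[str, FittedRegressor]:
    models: dict[str, FittedRegressor] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        models["mlp"] = fit_mlp(
            table, split, hidden_size=config.mlp_hidden, trainer=config.mlp_trainer,
            seed=config.mlp_seed,
            config=MLPTrainConfig(max_epochs=config.mlp_epochs),
        )
        models["rbf"] = fit_rbf_model(
            table, split, max_neurons=config.rbf_neurons, spread=config.rbf_spread,
            strategy=config.rbf_strategy, seed=config.mlp_seed,
        )
        models["svr"] = fit_svr_model(
            table, split,
            config=SVRConfig(C=config.svr_c, epsilon=config.svr_epsilon,
                             gamma=config.svr_gamma),
            seed=config.mlp_seed,
        )
    collected.extend(str(w.message) for w in caught)
    return models


def run_pipeline(config: RunConfig, outdir) -> RunArtifacts:
    """Execute all stages and write the artifact directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)
    (outdir / "curves").mkdir(exist_ok=True)
    collected_warnings: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                logger.info("stage %s finished in %.3fs", name, timings[name])

        return _Timer()

    with stage("data"):
        if config.data_source == "synthetic":
            table = generate_dataset(
                DEFAULT_CONFIG, n=config.n_samples, seed=config.data_seed
            )
        else:
            table = load_samples(config.data_source)
            if not table.has_target:
                raise ValueError("training data must include the hypericin column")
        save_samples(table, outdir / "dataset.csv")

    with stage("split"):
        split = split_dataset(table.n, config.split_fractions, config.split_seed)
        split.save(outdir / "split.json")

    with stage("train"):
        models = _train_all(config, table, split, collected_warnings)
        model_paths = {}
        for name, model in models.items():
            p = outdir / "models" / f"{name}.json"
            model.save(p)
            model_paths[name] = p

    with stage("evaluate"):
        reports = {
            name: evaluate_model(model, split, table, model_id=name)
            for name, model in models.items()
        }
        best_id, comparison = select_best(list(reports.values()))
        comparison.to_csv(outdir / "comparison.csv", index=False,
                          float_format=_CSV_FLOAT)
        pd.concat(
            [r.table.assign(model=name) for name, r in reports.items()]
        ).to_csv(outdir / "metrics.csv", float_format=_CSV_FLOAT)

    with stage("sensitivity"):
        stats = SampleStats.from_table(table.subset(split.train_idx))
        report = sensitivity_scores(
            models[best_id], stats, k=config.sensitivity_k,
            width=config.sensitivity_width, model_id=best_id,
        )
        report.table.to_csv(outdir / "sensitivity.csv", float_format=_CSV_FLOAT)
        for var in PREDICTOR_NAMES:
            curve, mono = response_curve(
                models[best_id], var, stats, k=config.sensitivity_k,
                width=config.sensitivity_width,
            )
            curve.attrs["monotonicity"] = mono
            curve.to_csv(outdir / "curves" / f"{var}.csv", index=False,
                         float_format=_CSV_FLOAT)

    config.to_yaml(outdir / "config_snapshot.yaml")
    log = {
        "config_hash": config.config_hash,
        "seeds": {
            "data": config.data_seed,
            "split": config.split_seed,
            "model": config.mlp_seed,
        },
        "selected_model": best_id,
        "stage_seconds": timings,
        "warnings": collected_warnings,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))

    return RunArtifacts(
        outdir=outdir,
        config=config,
        selected_model=best_id,
        model_paths=model_paths,
        reports=reports,
        comparison=comparison,
        sensitivity=report.table,
        warnings=collected_warnings,
    )


def predict_new(model_path, csv_path, out_path=None) -> pd.DataFrame:
    """Predict hypericin for new samples with any saved model.

    The output echoes the 13 input columns and appends ``hypericin_pred``
    (mg/g).  Inputs outside the model's training range trigger a warning
    naming the rows and columns — the prediction is still emitted, but the
    model is operating outside the habitat conditions it was fitted on.
    """
    model = load_model(model_path)
    table = load_samples(csv_path)
    X, _ = encode_features(table)

    lo, hi = model.scaler.feature_lo, model.scaler.feature_hi
    out_of_range = (X < lo) | (X > hi)
    if out_of_range.any():
        cols = [PREDICTOR_NAMES[j] for j in np.unique(np.where(out_of_range)[1])]
        rows = np.unique(np.where(out_of_range)[0]).tolist()
        warnings.warn(
            f"inputs outside the training range in column(s) {cols} "
            f"(row(s) {rows}); predictions are extrapolations",
            UserWarning,
            stacklevel=2,
        )

    preds = model.predict_matrix(X)
    result = table.data.loc[:, list(PREDICTOR_NAMES)].copy()
    result["hypericin_pred"] = preds
    if out_path is not None:
        result.to_csv(out_path, index=False, float_format=_CSV_FLOAT)
    return result
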