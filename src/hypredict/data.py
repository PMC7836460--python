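"""Schema, CSV I/O, feature encoding, scaling and dataset partitioning.

The study design measures 13 habitat/phenology predictors per *Hypericum
perforatum* sample — three landform variables, the phenological stage and
nine soil variables — plus the response, hypericin content in mg per g dry
mass.  All downstream regressors consume the fixed 13-column design matrix
produced here; the column order is frozen (``PREDICTOR_NAMES``) so that a
serialized model is unambiguous about which weight belongs to which
variable regardless of the column order of the input CSV.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSchema",
    "SampleTable",
    "FeatureScaler",
    "Split",
    "SchemaError",
    "DEFAULT_SCHEMA",
    "PREDICTOR_NAMES",
    "TARGET_NAME",
    "load_samples",
    "save_samples",
    "encode_features",
    "fit_scaler",
    "split_dataset",
]


class SchemaError(ValueError):
    """Raised when an input table does not conform to the variable schema."""


@dataclass(frozen=True)
class VariableSchema:
    """Description of one measured variable.

    Parameters
    ----------
    name : str
        Canonical identifier (snake_case).
    kind : {"continuous", "ordinal"}
        Ordinal variables are ordered categories stored as consecutive
        integer codes starting at 1 (hill aspect north→west, phenological
        stage vegetative→seed ripening).
    unit : str
        Physical unit, empty for dimensionless/coded variables.
    codes : dict[str, int] or None
        Label → code map for ordinal variables.
    bounds : tuple[float, float]
        Physical (min, max) range observed in the field study.
    """

    name: str
    kind: str
    unit: str = ""
    codes: Optional[dict[str, int]] = None
    bounds: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise SchemaError(f"unknown variable kind {self.kind!r}")
        lo, hi = self.bounds
        if not lo < hi:
            raise SchemaError(f"{self.name}: bounds min must be < max")
        if self.kind == "ordinal":
            if not self.codes:
                raise SchemaError(f"{self.name}: ordinal variable needs codes")
            vals = sorted(self.codes.values())
            if vals != list(range(1, len(vals) + 1)):
                raise SchemaError(
                    f"{self.name}: codes must be consecutive integers from 1"
                )

    @property
    def code_values(self) -> list[int]:
        return sorted(self.codes.values()) if self.codes else []

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "unit": self.unit,
            "codes": self.codes,
            "bounds": list(self.bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(
            name=d["name"],
            kind=d["kind"],
            unit=d.get("unit", ""),
            codes=d.get("codes"),
            bounds=tuple(d["bounds"]),
        )


ASPECT_CODES = {"north": 1, "east": 2, "south": 3, "west": 4}
PHENOLOGY_CODES = {"vegetative": 1, "flowering": 2, "seed_ripening": 3}

# Frozen design-matrix column order: landform, phenology, then soil.
DEFAULT_SCHEMA: tuple[VariableSchema, ...] = (
    VariableSchema("altitude", "continuous", "m", bounds=(1103, 3822)),
    VariableSchema("slope", "continuous", "%", bounds=(5, 35)),
    VariableSchema("aspect", "ordinal", codes=ASPECT_CODES, bounds=(1, 4)),
    VariableSchema("phenology", "ordinal", codes=PHENOLOGY_CODES, bounds=(1, 3)),
    VariableSchema("organic_carbon", "continuous", "%", bounds=(0, 2.6)),
    VariableSchema("total_nitrogen", "continuous", "%", bounds=(0.1, 0.57)),
    VariableSchema("phosphorus", "continuous", "ppm", bounds=(0.5, 5.7)),
    VariableSchema("potassium", "continuous", "ppm", bounds=(103, 287)),
    VariableSchema("sand", "continuous", "%", bounds=(35, 50)),
    VariableSchema("silt", "continuous", "%", bounds=(20, 50)),
    VariableSchema("clay", "continuous", "%", bounds=(5, 35)),
    VariableSchema("ec", "continuous", "dS/m", bounds=(0.02, 0.2)),
    VariableSchema("ph", "continuous", "", bounds=(6.2, 7.9)),
    VariableSchema("hypericin", "continuous", "mg/g", bounds=(0, 10)),
)

PREDICTOR_NAMES: tuple[str, ...] = tuple(v.name for v in DEFAULT_SCHEMA[:-1])
TARGET_NAME = "hypericin"
N_PREDICTORS = len(PREDICTOR_NAMES)

# Accepted CSV header spellings (normalized: lowercase, units stripped).
_ALIASES = {
    "hill_aspect": "aspect",
    "geographical_aspect": "aspect",
    "phenological_stage": "phenology",
    "phenological_stages": "phenology",
    "phenology_stage": "phenology",
    "total_n": "total_nitrogen",
    "absorbable_phosphor": "phosphorus",
    "absorbable_phosphorus": "phosphorus",
    "absorbable_potassium": "potassium",
    "organic_c": "organic_carbon",
    "electrical_conductivity": "ec",
    "acidity": "ph",
    "hypericin_content": "hypericin",
}


def _normalize_header(name: str) -> str:
    s = name.strip().lower()
    s = re.sub(r"\(.*?\)", "", s)  # drop units in parentheses
    s = re.sub(r"[^a-z0-9]+", "_", s).strip("_")
    return _ALIASES.get(s, s)


@dataclass
class SampleTable:
    """A table of samples conforming to the variable schema.

    ``data`` holds one column per schema variable that is present (the
    hypericin target is optional, e.g. for prediction-mode input); ordinal
    variables are stored as their integer codes.
    """

    data: pd.DataFrame
    schema: tuple[VariableSchema, ...] = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        for var in self.schema[:-1]:
            if var.name not in self.data.columns:
                raise SchemaError(f"missing predictor column {var.name!r}")
        self._validate_values()
        order = [v.name for v in self.schema if v.name in self.data.columns]
        self.data = self.data.loc[:, order].reset_index(drop=True)

    def _validate_values(self) -> None:
        for var in self.schema:
            if var.name not in self.data.columns:
                continue
            col = self.data[var.name]
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise SchemaError(f"row {row}: missing value for {var.name!r}")
            if var.kind == "ordinal":
                valid = set(var.code_values)
                bad = ~col.isin(valid)
                if bad.any():
                    row = int(bad.idxmax())
                    raise SchemaError(
                        f"row {row}: invalid code {col[row]!r} for {var.name!r}; "
                        f"valid codes are {sorted(valid)}"
                    )
        if TARGET_NAME in self.data.columns:
            if (self.data[TARGET_NAME] < 0).any():
                raise SchemaError("hypericin content must be >= 0")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def has_target(self) -> bool:
        return TARGET_NAME in self.data.columns

    def subset(self, idx: Sequence[int]) -> "SampleTable":
        return SampleTable(self.data.iloc[list(idx)].reset_index(drop=True), self.schema)

    def to_csv(self, path) -> None:
        save_samples(self, path)


def load_samples(path, schema: Sequence[VariableSchema] = DEFAULT_SCHEMA) -> SampleTable:
    """Read a sample CSV into a validated :class:`SampleTable`.

    Header matching is case-insensitive and tolerant of units in
    parentheses and common long-form names ("Hill aspect", "Total N (%)").
    Ordinal variables may be given either as integer codes or as text
    labels ("north" → 1, "flowering" → 2, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [_normalize_header(c) for c in raw.columns]
    schema = tuple(schema)
    known = {v.name: v for v in schema}

    missing = [v.name for v in schema[:-1] if v.name not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    out: dict[str, np.ndarray] = {}
    for name, var in known.items():
        if name not in raw.columns:
            continue
        col = raw[name].astype(str).str.strip()
        if var.kind == "ordinal":
            out[name] = _parse_ordinal(col, var)
        else:
            out[name] = _parse_numeric(col, name)
    return SampleTable(pd.DataFrame(out), schema)


def _parse_numeric(col: pd.Series, name: str) -> np.ndarray:
    try:
        return pd.to_numeric(col).to_numpy(dtype=float)
    except (ValueError, TypeError):
        for i, v in enumerate(col):
            try:
                float(v)
            except ValueError:
                raise SchemaError(
                    f"row {i}: cannot parse {v!r} as a number for column {name!r}"
                ) from None
        raise


def _parse_ordinal(col: pd.Series, var: VariableSchema) -> np.ndarray:
    values = np.empty(len(col), dtype=int)
    label_map = {k.lower(): v for k, v in (var.codes or {}).items()}
    label_map.update({k.replace("_", " "): v for k, v in list(label_map.items())})
    for i, v in enumerate(col):
        s = v.strip().lower()
        if s in label_map:
            values[i] = label_map[s]
            continue
        try:
            code = int(float(s))
        except ValueError:
            raise SchemaError(
                f"row {i}: unknown label {v!r} for {var.name!r}; "
                f"valid labels are {sorted(var.codes)}"
            ) from None
        values[i] = code
    return values


def save_samples(table: SampleTable, path) -> None:
    """Write a SampleTable as CSV with deterministic float formatting."""
    df = table.data.copy()
    with open(path, "w", newline="") as fh:
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = []
            for name, v in row.items():
                if float(v) == int(v):
                    cells.append(str(int(v)))
                else:
                    cells.append(repr(float(v)))
            fh.write(",".join(cells) + "\n")


def encode_features(
    table: SampleTable,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Build the (n, 13) design matrix and, if present, the target vector.

    Ordinal variables enter as their integer codes (the ordered numeric
    treatment the sensitivity trends rely on), not one-hot — the model
    input dimension is exactly 13.
    """
    X = table.data.loc[:, list(PREDICTOR_NAMES)].to_numpy(dtype=float)
    y = None
    if table.has_target:
        y = table.data[TARGET_NAME].to_numpy(dtype=float)
    return X, y


@dataclass
class FeatureScaler:
    """Min–max scaler mapping each training-data feature (and the target)
    onto [-1, 1]; constant columns map to 0.

    Fit on training rows only; models train and predict in scaled space and
    predictions are inverse-scaled back to mg/g before any metric is
    computed.
    """

    feature_lo: Optional[np.ndarray] = None
    feature_hi: Optional[np.ndarray] = None
    target_lo: Optional[float] = None
    target_hi: Optional[float] = None

    @property
    def fitted(self) -> bool:
        return self.feature_lo is not None

    def fit(self, X: np.ndarray, y: Optional[np.ndarray] = None) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.feature_lo = X.min(axis=0)
        self.feature_hi = X.max(axis=0)
        if y is not None:
            y = np.asarray(y, dtype=float)
            self.target_lo = float(y.min())
            self.target_hi = float(y.max())
        return self

    def _check(self) -> None:
        if not self.fitted:
            raise RuntimeError("scaler has not been fitted")

    @staticmethod
    def _scale(v, lo, hi):
        span = hi - lo
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(span > 0, -1.0 + 2.0 * (v - lo) / np.where(span > 0, span, 1.0), 0.0)
        return out

    @staticmethod
    def _unscale(v, lo, hi):
        return lo + (np.asarray(v) + 1.0) * (hi - lo) / 2.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check()
        return self._scale(np.asarray(X, dtype=float), self.feature_lo, self.feature_hi)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        self._check()
        return self._unscale(X, self.feature_lo, self.feature_hi)

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        self._check()
        if self.target_lo is None:
            raise RuntimeError("scaler was fitted without a target")
        return self._scale(np.asarray(y, dtype=float), self.target_lo, self.target_hi)

    def inverse_transform_target(self, y: np.ndarray) -> np.ndarray:
        self._check()
        if self.target_lo is None:
            raise RuntimeError("scaler was fitted without a target")
        return self._unscale(y, self.target_lo, self.target_hi)

    def to_dict(self) -> dict:
        self._check()
        return {
            "feature_lo": self.feature_lo.tolist(),
            "feature_hi": self.feature_hi.tolist(),
            "target_lo": self.target_lo,
            "target_hi": self.target_hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(
            feature_lo=np.asarray(d["feature_lo"], dtype=float),
            feature_hi=np.asarray(d["feature_hi"], dtype=float),
            target_lo=d["target_lo"],
            target_hi=d["target_hi"],
        )


def fit_scaler(X: np.ndarray, y: Optional[np.ndarray] = None) -> FeatureScaler:
    """Fit a [-1, 1] min–max scaler on (training) features and target."""
    return FeatureScaler().fit(X, y)


@dataclass(frozen=True)
class Split:
    """Disjoint train/validation/test row indices with the seed that made them."""

    train_idx: tuple[int, ...]
    val_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        all_idx = self.train_idx + self.val_idx + self.test_idx
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("split partitions overlap")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.val_idx) + len(self.test_idx)

    def to_dict(self) -> dict:
        return {
            "train_idx": list(self.train_idx),
            "val_idx": list(self.val_idx),
            "test_idx": list(self.test_idx),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Split":
        return cls(
            tuple(d["train_idx"]), tuple(d["val_idx"]), tuple(d["test_idx"]), d["seed"]
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "Split":
        return cls.from_dict(json.loads(Path(path).read_text()))


def split_dataset(
    n: int,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Split:
    """Seeded uniform random partition into train/validation/test.

    Sizes are floor allocations of ``n * fraction`` with the remaining rows
    assigned in the order train, validation, test, so the canonical n=100
    with (0.6, 0.2, 0.2) gives exactly (60, 20, 20).
    """
    if n < 3:
        raise ValueError("need at least 3 samples to populate all partitions")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    sizes = [int(np.floor(n * f)) for f in fractions]
    remainder = n - sum(sizes)
    for i in range(remainder):
        sizes[i % 3] += 1

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return Split(
        train_idx=tuple(int(i) for i in perm[:a]),
        val_idx=tuple(int(i) for i in perm[a:b]),
        test_idx=tuple(int(i) for i in perm[b:]),
        seed=int(seed),
    )
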