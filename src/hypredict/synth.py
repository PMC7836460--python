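"""Synthetic habitat-sample generator calibrated to the field study's
printed summary statistics.

The original 100 field samples are not publicly deposited, so the pipeline
is exercised on synthetic tables that reproduce the study's per-variable
marginals (mean, standard error, min, max; SD = SE x sqrt(100)) and its
qualitative response structure: hypericin rises linearly with phenological
stage, total soil nitrogen and altitude, rises with hill aspect ordered
north -> east -> south -> west (with little difference between south and
west), saturates in soil organic carbon above a 1.5 % breakpoint, and is
insensitive to the remaining eight variables.

Continuous covariates are drawn from independent truncated normals whose
bounds are the printed (min, max).  Truncation shifts the mean of a
clipped normal, so the parent location of each marginal is solved
(deterministically, by root finding) such that the *truncated* mean equals
the printed mean; the parent scale is kept at the printed SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import (
    DEFAULT_SCHEMA,
    PREDICTOR_NAMES,
    TARGET_NAME,
    SampleTable,
)

__all__ = [
    "ContinuousMarginal",
    "OrdinalMarginal",
    "EffectConfig",
    "GeneratorConfig",
    "DEFAULT_CONFIG",
    "sample_covariates",
    "true_response",
    "generate_dataset",
    "summarize_table",
]


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class ContinuousMarginal:
    """Truncated-normal marginal: target mean, parent SD and hard bounds."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError("sd must be positive")
        if not self.lo < self.mean < self.hi:
            raise ConfigError("need min < mean < max")


@dataclass(frozen=True)
class OrdinalMarginal:
    """Category probabilities over consecutive codes starting at 1."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigError("category probabilities must be >= 0 and sum to 1")

    @property
    def codes(self) -> np.ndarray:
        return np.arange(1, len(self.probs) + 1)

    @property
    def mean(self) -> float:
        return float(np.dot(self.codes, self.probs))


@dataclass(frozen=True)
class EffectConfig:
    """Additive noise-free response surface for hypericin (mg/g).

    Five active drivers; the other eight predictors have zero effect.
    Organic carbon is a two-piece linear ("broken stick") term that
    flattens above ``oc_breakpoint``; hill aspect contributes a per-level
    increment that rises north -> west with a small south -> west step.
    """

    intercept: float = 1.0631
    altitude_slope: float = 3.7e-5        # mg/g per m
    total_nitrogen_slope: float = 0.5     # mg/g per % N
    phenology_step: float = 0.12          # mg/g per stage above vegetative
    oc_breakpoint: float = 1.5            # % organic carbon
    oc_slope_below: float = 0.12          # mg/g per % below the breakpoint
    oc_slope_above: float = 0.0
    aspect_increments: tuple[float, float, float, float] = (0.0, 0.07, 0.12, 0.14)

    def __post_init__(self) -> None:
        if min(self.altitude_slope, self.total_nitrogen_slope, self.phenology_step) <= 0:
            raise ConfigError("active linear effects must be positive")
        inc = self.aspect_increments
        if any(b < a for a, b in zip(inc, inc[1:])):
            raise ConfigError("aspect increments must be nondecreasing")


# Printed field-study marginals: mean +/- SE (min, max), n = 100, SD = 10*SE.
_CONTINUOUS_MARGINALS: dict[str, ContinuousMarginal] = {
    "altitude": ContinuousMarginal(2338.21, 753.3, 1103, 3822),
    "slope": ContinuousMarginal(19.5, 6.3, 5, 35),
    "organic_carbon": ContinuousMarginal(0.85, 0.6, 0, 2.6),
    "total_nitrogen": ContinuousMarginal(0.34, 0.1, 0.1, 0.57),
    "phosphorus": ContinuousMarginal(3.11, 1.3, 0.5, 5.7),
    "potassium": ContinuousMarginal(206.93, 55.4, 103, 287),
    "sand": ContinuousMarginal(42.5, 3.8, 35, 50),
    "silt": ContinuousMarginal(38.1, 6.1, 20, 50),
    "clay": ContinuousMarginal(19.4, 6.5, 5, 35),
    "ec": ContinuousMarginal(0.09, 0.03, 0.02, 0.2),
    "ph": ContinuousMarginal(7.23, 0.5, 6.2, 7.9),
}

# Ordinal marginals chosen to match the printed means exactly:
# aspect mean 2.63 over codes 1..4, phenological stage mean 1.99 over 1..3.
_ORDINAL_MARGINALS: dict[str, OrdinalMarginal] = {
    "aspect": OrdinalMarginal((0.15, 0.25, 0.42, 0.18)),
    "phenology": OrdinalMarginal((0.34, 0.33, 0.33)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator specification: marginals, effects, noise, defaults."""

    continuous: dict[str, ContinuousMarginal] = field(
        default_factory=lambda: dict(_CONTINUOUS_MARGINALS)
    )
    ordinal: dict[str, OrdinalMarginal] = field(
        default_factory=lambda: dict(_ORDINAL_MARGINALS)
    )
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise_sd: float = 0.05  # residual SD of hypericin, mg/g
    n_default: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        expected = set(PREDICTOR_NAMES)
        got = set(self.continuous) | set(self.ordinal)
        if got != expected:
            raise ConfigError(
                f"marginals must cover exactly the 13 predictors; "
                f"missing {expected - got}, extra {got - expected}"
            )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


DEFAULT_CONFIG = GeneratorConfig()


@lru_cache(maxsize=64)
def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Parent location of a truncated normal whose truncated mean is `mean`."""

    def gap(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - mean

    return float(optimize.brentq(gap, lo - 5 * sd, hi + 5 * sd, xtol=1e-10))


def sample_covariates(
    config: GeneratorConfig = DEFAULT_CONFIG,
    n: Optional[int] = None,
    seed: Optional[int] = None,
) -> SampleTable:
    """Draw `n` covariate rows (no target), reproducibly by seed.

    Variables are sampled independently, in the frozen predictor order, from
    one seeded generator, so equal (config, n, seed) give identical tables.
    """
    n = config.n_default if n is None else int(n)
    if n < 1:
        raise ConfigError("n must be >= 1")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    cols: dict[str, np.ndarray] = {}
    for name in PREDICTOR_NAMES:
        if name in config.continuous:
            m = config.continuous[name]
            mu = _calibrated_loc(m.mean, m.sd, m.lo, m.hi)
            a, b = (m.lo - mu) / m.sd, (m.hi - mu) / m.sd
            cols[name] = stats.truncnorm.rvs(
                a, b, loc=mu, scale=m.sd, size=n, random_state=rng
            )
        else:
            m = config.ordinal[name]
            cols[name] = rng.choice(m.codes, size=n, p=m.probs)
    return SampleTable(pd.DataFrame(cols))


def true_response(
    covariates: SampleTable | pd.DataFrame,
    effects: EffectConfig = DEFAULT_CONFIG.effects,
) -> np.ndarray:
    """Noise-free hypericin response (mg/g) of the additive surface.

    intercept + altitude + total-N + phenology linear terms
    + broken-stick organic-carbon term + aspect level increment,
    floored at the physical 0.
    """
    df = covariates.data if isinstance(covariates, SampleTable) else covariates
    e = effects
    oc = df["organic_carbon"].to_numpy(dtype=float)
    oc_term = np.where(
        oc <= e.oc_breakpoint,
        e.oc_slope_below * oc,
        e.oc_slope_below * e.oc_breakpoint + e.oc_slope_above * (oc - e.oc_breakpoint),
    )
    aspect = df["aspect"].to_numpy(dtype=int)
    resp = (
        e.intercept
        + e.altitude_slope * df["altitude"].to_numpy(dtype=float)
        + e.total_nitrogen_slope * df["total_nitrogen"].to_numpy(dtype=float)
        + e.phenology_step * (df["phenology"].to_numpy(dtype=float) - 1.0)
        + oc_term
        + np.take(e.aspect_increments, aspect - 1)
    )
    return np.maximum(resp, 0.0)


def generate_dataset(
    config: GeneratorConfig = DEFAULT_CONFIG,
    n: Optional[int] = None,
    seed: Optional[int] = None,
) -> SampleTable:
    """Covariates plus hypericin = true_response + N(0, noise_sd), clipped at 0."""
    n = config.n_default if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    table = sample_covariates(config, n, seed)
    resp = true_response(table, config.effects)
    # separate stream so the covariate draw is unchanged by noise_sd
    noise_rng = np.random.default_rng((int(seed) + 1) % (2**31))
    y = resp + noise_rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else resp
    df = table.data.copy()
    df[TARGET_NAME] = np.maximum(y, 0.0)
    return SampleTable(df)


def summarize_table(table: SampleTable) -> pd.DataFrame:
    """Per-variable mean, standard error (sd/sqrt(n)), min and max.

    Formatted like the field study's summary table so synthetic marginals
    can be compared against the printed values directly.
    """
    if table.n < 2:
        raise ValueError("need at least 2 rows to summarize")
    rows = []
    for name in table.data.columns:
        col = table.data[name].to_numpy(dtype=float)
        rows.append(
            {
                "variable": name,
                "mean": float(col.mean()),
                "se": float(col.std(ddof=1) / np.sqrt(len(col))),
                "min": float(col.min()),
                "max": float(col.max()),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
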