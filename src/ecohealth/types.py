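"""Core domain types for coastal ecosystem carrying-capacity assessment.

The assessment treats a coastal zone as a three-subsystem state space
(economic contribution, ecological services, human activity). Each
subsystem is measured by a set of indicators observed annually; the
carrying capacity of the system in a given year is the Euclidean modulus
of the vector of weighted, normalized indicator values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Subsystem",
    "Direction",
    "CarryingType",
    "Trend",
    "WarningLevel",
    "WarningDegree",
    "HealthLevel",
    "IndicatorDefinition",
    "IndicatorPanel",
    "NormalizedPanel",
    "WeightVector",
    "CarryingAssessment",
    "DiagnosisRecord",
    "PipelineConfig",
    "WARNING_TABLE",
    "HEALTH_TABLE",
]


class Subsystem(enum.Enum):
    """The three axes of the carrying-capacity state space."""

    ECONOMIC = "economic"
    ECOLOGICAL = "ecological"
    HUMAN = "human"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Direction(enum.Enum):
    """Whether larger raw values load the system more (positive) or less."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CarryingType(enum.Enum):
    """Five carrying bands defined by multiples of the ideal modulus."""

    LIGHT_LOAD = "light load"
    LOADABLE = "loadable"
    CRITICAL_OVERLOAD = "critical overload"
    OVERLOAD = "overload"
    SEVERE_OVERLOAD = "severe overload"

    def __str__(self) -> str:
        return self.value


class Trend(enum.Enum):
    """Year-on-year movement of the carrying modulus."""

    AGGRAVATED = "aggravated"  # rose relative to the previous year
    SLOWING = "slowing"  # fell (or tied, under the default tie rule)
    UNDEFINED = "undefined"  # no predecessor and the config says so

    def __str__(self) -> str:
        return self.value


class WarningLevel(enum.Enum):
    GREEN = "green"
    BLUE = "blue"
    YELLOW = "yellow"
    ORANGE = "orange"
    RED = "red"

    def __str__(self) -> str:
        return self.value


class WarningDegree(enum.Enum):
    NO = "no"
    LIGHT = "light"
    MEDIUM = "medium"
    HEAVY = "heavy"
    EXTREMELY_HEAVY = "extremely heavy"

    def __str__(self) -> str:
        return self.value


class HealthLevel(enum.Enum):
    VERY_HEALTHY = "very healthy"
    HEALTHY = "healthy"
    SUB_HEALTH = "sub-health"
    UNHEALTHY = "unhealthy"
    MORBID = "morbid"

    def __str__(self) -> str:
        return self.value


#: (warning level, warning degree) keyed by (carrying band group, trend).
#: Light load and loadable are "no overload": green regardless of trend.
#: Severe overload has no separate warning row; it routes through the
#: overload branch (orange/red) while keeping its own carrying label.
WARNING_TABLE: Mapping[tuple[CarryingType, Trend], tuple[WarningLevel, WarningDegree]] = {
    (CarryingType.CRITICAL_OVERLOAD, Trend.SLOWING): (WarningLevel.BLUE, WarningDegree.LIGHT),
    (CarryingType.CRITICAL_OVERLOAD, Trend.AGGRAVATED): (WarningLevel.YELLOW, WarningDegree.MEDIUM),
    (CarryingType.OVERLOAD, Trend.SLOWING): (WarningLevel.ORANGE, WarningDegree.HEAVY),
    (CarryingType.OVERLOAD, Trend.AGGRAVATED): (WarningLevel.RED, WarningDegree.EXTREMELY_HEAVY),
}

#: One-to-one mapping from warning degree to health level.
HEALTH_TABLE: Mapping[WarningDegree, HealthLevel] = {
    WarningDegree.NO: HealthLevel.VERY_HEALTHY,
    WarningDegree.LIGHT: HealthLevel.HEALTHY,
    WarningDegree.MEDIUM: HealthLevel.SUB_HEALTH,
    WarningDegree.HEAVY: HealthLevel.UNHEALTHY,
    WarningDegree.EXTREMELY_HEAVY: HealthLevel.MORBID,
}


@dataclass(frozen=True)
class IndicatorDefinition:
    """One measured indicator: identity, subsystem membership, direction."""

    id: str
    name: str
    subsystem: Subsystem
    direction: Direction
    units: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("indicator id must be non-empty")


def _check_definitions(definitions: Sequence[IndicatorDefinition]) -> dict[str, IndicatorDefinition]:
    by_id: dict[str, IndicatorDefinition] = {}
    for d in definitions:
        if d.id in by_id:
            raise ValueError(f"duplicate indicator id: {d.id!r}")
        by_id[d.id] = d
    return by_id


@dataclass
class IndicatorPanel:
    """A year x indicator matrix of raw observations.

    ``values`` is indexed by calendar year with one column per indicator
    id; NaN cells are missing observations. Metadata travels with the
    panel so downstream stages can partition columns by subsystem and
    orient them by direction.
    """

    values: pd.DataFrame
    definitions: Sequence[IndicatorDefinition]

    def __post_init__(self) -> None:
        self.definitions = tuple(self.definitions)
        by_id = _check_definitions(self.definitions)
        missing_meta = [c for c in self.values.columns if c not in by_id]
        if missing_meta:
            raise ValueError(f"columns without metadata: {missing_meta}")
        years = self.values.index.to_numpy()
        if len(years) < 1:
            raise ValueError("panel must contain at least one year")
        if not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.values.index]

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    def definition(self, indicator_id: str) -> IndicatorDefinition:
        for d in self.definitions:
            if d.id == indicator_id:
                return d
        raise KeyError(indicator_id)

    def subsystem_of(self) -> pd.Series:
        """Series mapping indicator id -> Subsystem, in column order."""
        return pd.Series(
            {d.id: d.subsystem for d in self.definitions if d.id in self.values.columns}
        ).reindex(self.values.columns)

    def with_values(self, values: pd.DataFrame) -> "IndicatorPanel":
        return replace(self, values=values)


@dataclass
class NormalizedPanel(IndicatorPanel):
    """An IndicatorPanel whose values are range-normalized into [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("normalized panel must have no missing cells")
        if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
            raise ValueError("normalized values must lie in [0, 1]")


@dataclass
class WeightVector:
    """Per-indicator nonnegative weights, summing to 1 within each subsystem."""

    weights: pd.Series  # indexed by indicator id
    subsystems: pd.Series  # indicator id -> Subsystem

    def __post_init__(self) -> None:
        self.weights = self.weights.astype(float)
        if (self.weights < 0).any():
            bad = self.weights[self.weights < 0].index.tolist()
            raise ValueError(f"negative weights for: {bad}")
        if not self.weights.index.equals(self.subsystems.index):
            self.subsystems = self.subsystems.reindex(self.weights.index)
            if self.subsystems.isna().any():
                raise ValueError("every weighted indicator needs a subsystem")
        for sub in Subsystem:
            w = self.for_subsystem(sub)
            if len(w) and abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"weights for subsystem {sub.value!r} sum to {w.sum():.12f}, expected 1"
                )

    def for_subsystem(self, subsystem: Subsystem) -> pd.Series:
        return self.weights[self.subsystems == subsystem]

    @property
    def counts(self) -> dict[Subsystem, int]:
        return {sub: int((self.subsystems == sub).sum()) for sub in Subsystem}


@dataclass
class CarryingAssessment:
    """Per-year subsystem and overall carrying moduli plus ideal-state moduli.

    ``moduli`` is indexed by year with columns ecc_economic,
    ecc_ecological, ecc_human, ecc. ``ideal`` carries the same four
    quantities for the ideal state (ECC* and its subsystem parts).
    """

    moduli: pd.DataFrame
    ideal: Mapping[str, float]
    ideal_strategy: str = "mean"

    SUB_COLUMNS = {
        Subsystem.ECONOMIC: "ecc_economic",
        Subsystem.ECOLOGICAL: "ecc_ecological",
        Subsystem.HUMAN: "ecc_human",
    }

    def __post_init__(self) -> None:
        required = set(self.SUB_COLUMNS.values()) | {"ecc"}
        if not required.issubset(self.moduli.columns):
            raise ValueError(f"moduli table needs columns {sorted(required)}")
        if (self.moduli[sorted(required)] < 0).to_numpy().any():
            raise ValueError("moduli must be nonnegative")
        sub = self.moduli[list(self.SUB_COLUMNS.values())].to_numpy()
        rss = np.sqrt((sub**2).sum(axis=1))
        if not np.allclose(rss, self.moduli["ecc"].to_numpy(), atol=1e-12, rtol=0):
            raise ValueError("overall modulus must decompose into subsystem moduli")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.moduli.index]

    @property
    def ecc(self) -> pd.Series:
        return self.moduli["ecc"]

    @property
    def ecc_star(self) -> float:
        return float(self.ideal["ecc"])

    def subsystem_series(self, subsystem: Subsystem) -> pd.Series:
        return self.moduli[self.SUB_COLUMNS[subsystem]]

    def ideal_subsystem(self, subsystem: Subsystem) -> float:
        return float(self.ideal[self.SUB_COLUMNS[subsystem]])


@dataclass(frozen=True)
class DiagnosisRecord:
    """The full per-year diagnosis: band -> trend -> warning -> health."""

    year: int
    carrying_type: CarryingType
    trend: Trend
    warning_level: WarningLevel
    warning_degree: WarningDegree
    health_level: HealthLevel

    def __post_init__(self) -> None:
        if HEALTH_TABLE[self.warning_degree] is not self.health_level:
            raise ValueError(
                f"{self.year}: degree {self.warning_degree} cannot pair with {self.health_level}"
            )
        green_types = {CarryingType.LIGHT_LOAD, CarryingType.LOADABLE}
        if (self.warning_level is WarningLevel.GREEN) != (self.carrying_type in green_types):
            raise ValueError(
                f"{self.year}: green warning iff carrying type is light load/loadable"
            )


@dataclass
class PipelineConfig:
    """Tunable pipeline settings with the documented defaults.

    band_multipliers : thresholds on |ECC|/|ECC*| separating the five
        carrying bands (defaults 0.8, 1.0, 1.2, 1.4 — the +/-20% tolerance
        interval around the ideal state).
    ideal_strategy : how per-indicator ideal values are chosen ("mean"
        over the study period, "max", or "fixed" user-supplied values).
    cv_basis : whether coefficient-of-variation weights are computed on
        raw or normalized data.
    smoothing_alpha : exponential-smoothing coefficient for imputation.
    trend_tie_rule / first_year_rule : how equal consecutive moduli and
        the predecessor-less first year are classified.
    contribution_definition : "linear" (mean loads) or "squared" shares.
    report_decimals : display rounding at the reporting boundary only.
    """

    band_multipliers: tuple[float, float, float, float] = (0.8, 1.0, 1.2, 1.4)
    ideal_strategy: str = "mean"
    fixed_ideal_values: Mapping[str, float] | None = None
    cv_basis: str = "raw"
    smoothing_alpha: float = 0.5
    trend_tie_rule: Trend = Trend.SLOWING
    first_year_rule: Trend = Trend.AGGRAVATED
    contribution_definition: str = "linear"
    report_decimals: int = 3

    def __post_init__(self) -> None:
        m = tuple(float(x) for x in self.band_multipliers)
        if len(m) != 4 or any(x <= 0 for x in m) or any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("band multipliers must be four strictly increasing positives")
        self.band_multipliers = m
        if self.ideal_strategy not in {"mean", "max", "fixed"}:
            raise ValueError(f"unknown ideal strategy: {self.ideal_strategy!r}")
        if self.cv_basis not in {"raw", "normalized"}:
            raise ValueError(f"unknown CV basis: {self.cv_basis!r}")
        if not (0 < self.smoothing_alpha <= 1):
            raise ValueError("smoothing coefficient must be in (0, 1]")
        if self.contribution_definition not in {"linear", "squared"}:
            raise ValueError(f"unknown contribution definition: {self.contribution_definition!r}")
        if isinstance(self.trend_tie_rule, str):
            self.trend_tie_rule = Trend(self.trend_tie_rule)
        if isinstance(self.first_year_rule, str):
            self.first_year_rule = Trend(self.first_year_rule)
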