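"""The diagnosis chain: carrying band -> trend -> warning -> health level.

A year's overall modulus ECC is banded against multiples of the ideal
modulus ECC* (0.8/1.0/1.2/1.4 by default, i.e. a +/-20% tolerance
interval around the ideal state); the band plus the year-on-year trend
determine a five-color early-warning level and degree, which maps
one-to-one onto a five-state health level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .types import (
    CarryingAssessment,
    CarryingType,
    DiagnosisRecord,
    HealthLevel,
    PipelineConfig,
    Subsystem,
    Trend,
    WarningDegree,
    WarningLevel,
    HEALTH_TABLE,
    WARNING_TABLE,
)

logger = logging.getLogger("ecohealth")

__all__ = [
    "BandScheme",
    "classify_carrying",
    "assess_trend",
    "warning_level",
    "health_level",
    "diagnose_series",
    "subsystem_diagnosis",
]

_BAND_LABELS = (
    CarryingType.LIGHT_LOAD,
    CarryingType.LOADABLE,
    CarryingType.CRITICAL_OVERLOAD,
    CarryingType.OVERLOAD,
    CarryingType.SEVERE_OVERLOAD,
)

#: Carrying types the warning table treats as "no overload" (green).
GREEN_TYPES = {CarryingType.LIGHT_LOAD, CarryingType.LOADABLE}


@dataclass(frozen=True)
class BandScheme:
    """Thresholds on |ECC| as multiples of |ECC*| with left-open,
    right-closed intervals: (m_k * ECC*, m_{k+1} * ECC*]."""

    multipliers: tuple[float, float, float, float] = (0.8, 1.0, 1.2, 1.4)

    def __post_init__(self) -> None:
        m = self.multipliers
        if len(m) != 4 or any(x <= 0 for x in m) or any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("band multipliers must be four strictly increasing positives")

    def classify(self, ecc: float, ecc_star: float) -> CarryingType:
        if ecc_star <= 0:
            raise ValueError("ideal modulus must be positive")
        if ecc < 0:
            raise ValueError("modulus must be nonnegative")
        ratio = ecc / ecc_star
        for mult, label in zip(self.multipliers, _BAND_LABELS):
            if ratio <= mult:
                return label
        return CarryingType.SEVERE_OVERLOAD

    def midpoint_ratio(self, band: CarryingType) -> float:
        """A ratio safely inside the given band (used by scenario builders)."""
        m = self.multipliers
        edges = {
            CarryingType.LIGHT_LOAD: m[0] / 2,
            CarryingType.LOADABLE: (m[0] + m[1]) / 2,
            CarryingType.CRITICAL_OVERLOAD: (m[1] + m[2]) / 2,
            CarryingType.OVERLOAD: (m[2] + m[3]) / 2,
            CarryingType.SEVERE_OVERLOAD: m[3] + (m[3] - m[2]) / 2,
        }
        return edges[band]


def classify_carrying(
    ecc: float, ecc_star: float, scheme: BandScheme | None = None
) -> CarryingType:
    """Band-classify a modulus against the ideal modulus.

    Intervals are left-open, right-closed: a modulus exactly at
    1.2 * ECC* is still critical overload.
    """
    return (scheme or BandScheme()).classify(ecc, ecc_star)


def assess_trend(
    current: float,
    previous: float | None,
    tie_rule: Trend = Trend.SLOWING,
    first_year_rule: Trend = Trend.AGGRAVATED,
) -> Trend:
    """Year-on-year movement: rose -> aggravated, fell -> slowing.

    An exact tie and a missing predecessor are genuinely ambiguous; both
    default to the documented lenient/conservative conventions and are
    configurable.
    """
    if previous is None:
        logger.info("no predecessor year; trend defaulted to %s", first_year_rule)
        return first_year_rule
    if current > previous:
        return Trend.AGGRAVATED
    if current < previous:
        return Trend.SLOWING
    return tie_rule


def warning_level(
    carrying_type: CarryingType, trend: Trend
) -> tuple[WarningLevel, WarningDegree]:
    """Early-warning level and degree for a (band, trend) pair.

    Light load / loadable are "no overload": green, trend ignored.
    Severe overload routes through the overload branch (orange/red).
    An undefined trend is resolved as aggravated (the conservative
    reading) for warning purposes.
    """
    if carrying_type in GREEN_TYPES:
        return WarningLevel.GREEN, WarningDegree.NO
    lookup_type = (
        CarryingType.OVERLOAD
        if carrying_type is CarryingType.SEVERE_OVERLOAD
        else carrying_type
    )
    lookup_trend = Trend.AGGRAVATED if trend is Trend.UNDEFINED else trend
    return WARNING_TABLE[(lookup_type, lookup_trend)]


def health_level(degree: WarningDegree) -> HealthLevel:
    """Health level mapped one-to-one from the warning degree."""
    return HEALTH_TABLE[degree]


def diagnose_series(
    assessment: CarryingAssessment, config: PipelineConfig | None = None
) -> list[DiagnosisRecord]:
    """Run the full chain over the yearly overall moduli.

    Per year: band-classify ECC against ECC*, assess the trend against
    the previous year's ECC, look up the warning level/degree and map to
    the health level. Requires at least two years so every year past the
    first has a real predecessor.
    """
    config = config or PipelineConfig()
    years = assessment.years
    if len(years) < 2:
        raise ValueError("trend assessment needs at least two years")
    scheme = BandScheme(config.band_multipliers)
    ecc = assessment.ecc
    records = []
    prev: float | None = None
    for year in years:
        value = float(ecc.loc[year])
        ctype = scheme.classify(value, assessment.ecc_star)
        trend = assess_trend(value, prev, config.trend_tie_rule, config.first_year_rule)
        level, degree = warning_level(ctype, trend)
        records.append(
            DiagnosisRecord(
                year=year,
                carrying_type=ctype,
                trend=trend,
                warning_level=level,
                warning_degree=degree,
                health_level=health_level(degree),
            )
        )
        prev = value
    return records


def subsystem_diagnosis(
    assessment: CarryingAssessment, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-subsystem carrying types with trend arrows, one row per year.

    Mirrors the printed subsystem table: the arrow is shown only for
    critical overload and overload (green bands and severe overload are
    printed bare).
    """
    config = config or PipelineConfig()
    scheme = BandScheme(config.band_multipliers)
    out = pd.DataFrame(index=assessment.moduli.index)
    for sub, col in CarryingAssessment.SUB_COLUMNS.items():
        series = assessment.subsystem_series(sub)
        star = assessment.ideal_subsystem(sub)
        labels = []
        prev: float | None = None
        for year in assessment.years:
            value = float(series.loc[year])
            ctype = scheme.classify(value, star)
            trend = assess_trend(value, prev, config.trend_tie_rule, config.first_year_rule)
            if ctype in GREEN_TYPES or ctype is CarryingType.SEVERE_OVERLOAD:
                labels.append(ctype.value)
            else:
                arrow = "↗" if trend is Trend.AGGRAVATED else "↘"
                labels.append(f"{ctype.value} ({arrow})")
            prev = value
        out[sub.value] = labels
    return out
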