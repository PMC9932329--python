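"""The published Shandong Province (2007–2019) assessment as a fixture.

The original yearbook panel behind the published study is not deposited,
but the study's printed intermediate results are: indicator weights, the
per-subsystem carrying moduli with their ideal values, the overall
carrying-capacity series with its ideal modulus, and the final
warning/health diagnosis. Those tables are embedded here verbatim so the
aggregation, classification and diagnosis stages can be exercised and
cross-checked without any external data.

Indicator directions are NOT stated in the published index system; the
default assignment shipped here (pollution discharges, beach-garbage
density, class-IV seawater share and population density negative, all
others positive) is an editorial reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .types import (
    CarryingType,
    Direction,
    IndicatorDefinition,
    Subsystem,
    Trend,
    WarningDegree,
    WarningLevel,
    HealthLevel,
)

__all__ = ["ShandongFixture", "load_fixture_shandong", "shandong_definitions"]

YEARS = list(range(2007, 2020))

# Indicator weights (coefficient-of-variation method, as published).
_WEIGHTS_ECONOMIC = {
    "X_1": 0.121, "X_2": 0.114, "X_3": 0.019, "X_4": 0.028, "X_5": 0.033,
    "X_6": 0.045, "X_7": 0.050, "X_8": 0.179, "X_9": 0.062, "X_10": 0.126,
    "X_11": 0.104, "X_12": 0.060, "X_13": 0.058,
}
_WEIGHTS_ECOLOGICAL = {
    "Y_1": 0.050, "Y_2": 0.091, "Y_3": 0.035, "Y_4": 0.141, "Y_5": 0.102,
    "Y_6": 0.046, "Y_7": 0.057, "Y_8": 0.021, "Y_9": 0.050, "Y_10": 0.036,
    "Y_11": 0.157, "Y_12": 0.101, "Y_13": 0.113,
}
_WEIGHTS_HUMAN = {
    "Z_1": 0.006, "Z_2": 0.081, "Z_3": 0.188, "Z_4": 0.169, "Z_5": 0.084,
    "Z_6": 0.024, "Z_7": 0.027, "Z_8": 0.055, "Z_9": 0.081, "Z_10": 0.077,
    "Z_11": 0.087, "Z_12": 0.062, "Z_13": 0.059,
}

# Yearly subsystem carrying moduli and their ideal values.
_SUBSYSTEM_MODULI = {
    Subsystem.ECONOMIC: [0.030, 0.027, 0.034, 0.037, 0.047, 0.055, 0.070,
                         0.082, 0.072, 0.070, 0.073, 0.071, 0.065],
    Subsystem.ECOLOGICAL: [0.045, 0.062, 0.050, 0.053, 0.051, 0.056, 0.050,
                           0.051, 0.052, 0.050, 0.056, 0.062, 0.052],
    Subsystem.HUMAN: [0.074, 0.078, 0.076, 0.086, 0.106, 0.072, 0.084,
                      0.098, 0.092, 0.107, 0.091, 0.098, 0.100],
}
_SUBSYSTEM_IDEALS = {
    Subsystem.ECONOMIC: 0.0504,
    Subsystem.ECOLOGICAL: 0.0461,
    Subsystem.HUMAN: 0.0795,
}

# Printed per-subsystem carrying types (trend arrows dropped; they are
# recoverable from the modulus series).
_T = CarryingType
_SUBSYSTEM_TYPES = {
    Subsystem.ECONOMIC: [
        _T.LIGHT_LOAD, _T.LIGHT_LOAD, _T.LIGHT_LOAD, _T.LIGHT_LOAD,
        _T.LOADABLE, _T.CRITICAL_OVERLOAD, _T.OVERLOAD, _T.SEVERE_OVERLOAD,
        _T.SEVERE_OVERLOAD, _T.OVERLOAD, _T.SEVERE_OVERLOAD, _T.OVERLOAD,
        _T.OVERLOAD,
    ],
    Subsystem.ECOLOGICAL: [
        _T.LIGHT_LOAD, _T.OVERLOAD, _T.CRITICAL_OVERLOAD, _T.CRITICAL_OVERLOAD,
        _T.CRITICAL_OVERLOAD, _T.OVERLOAD, _T.CRITICAL_OVERLOAD,
        _T.CRITICAL_OVERLOAD, _T.CRITICAL_OVERLOAD, _T.CRITICAL_OVERLOAD,
        _T.OVERLOAD, _T.OVERLOAD, _T.CRITICAL_OVERLOAD,
    ],
    Subsystem.HUMAN: [
        _T.LOADABLE, _T.LOADABLE, _T.LOADABLE, _T.CRITICAL_OVERLOAD,
        _T.OVERLOAD, _T.LOADABLE, _T.CRITICAL_OVERLOAD, _T.OVERLOAD,
        _T.CRITICAL_OVERLOAD, _T.OVERLOAD, _T.CRITICAL_OVERLOAD,
        _T.OVERLOAD, _T.OVERLOAD,
    ],
}

# Overall carrying capacity series and ideal modulus.
_ECC = [0.092, 0.104, 0.097, 0.107, 0.127, 0.106, 0.121,
        0.137, 0.128, 0.138, 0.130, 0.136, 0.130]
_ECC_STAR = 0.1048
_ECC_TYPES = [
    _T.LOADABLE, _T.LOADABLE, _T.LOADABLE, _T.CRITICAL_OVERLOAD,
    _T.CRITICAL_OVERLOAD, _T.CRITICAL_OVERLOAD, _T.CRITICAL_OVERLOAD,
    _T.OVERLOAD, _T.OVERLOAD, _T.OVERLOAD, _T.OVERLOAD, _T.OVERLOAD,
    _T.OVERLOAD,
]

# Published diagnosis: trend arrow, warning level/degree, health level.
# Green (loadable) years print no arrow; stored as None.
_TRENDS: list[Trend | None] = [
    None, None, None,
    Trend.AGGRAVATED, Trend.AGGRAVATED, Trend.SLOWING, Trend.AGGRAVATED,
    Trend.AGGRAVATED, Trend.SLOWING, Trend.AGGRAVATED, Trend.SLOWING,
    Trend.AGGRAVATED, Trend.SLOWING,
]
_WL, _WD, _HL = WarningLevel, WarningDegree, HealthLevel
_WARNING_LEVELS = [
    _WL.GREEN, _WL.GREEN, _WL.GREEN, _WL.YELLOW, _WL.YELLOW, _WL.BLUE,
    _WL.YELLOW, _WL.RED, _WL.ORANGE, _WL.RED, _WL.ORANGE, _WL.RED, _WL.ORANGE,
]
_WARNING_DEGREES = [
    _WD.NO, _WD.NO, _WD.NO, _WD.MEDIUM, _WD.MEDIUM, _WD.LIGHT, _WD.MEDIUM,
    _WD.EXTREMELY_HEAVY, _WD.HEAVY, _WD.EXTREMELY_HEAVY, _WD.HEAVY,
    _WD.EXTREMELY_HEAVY, _WD.HEAVY,
]
_HEALTH_LEVELS = [
    _HL.VERY_HEALTHY, _HL.VERY_HEALTHY, _HL.VERY_HEALTHY, _HL.SUB_HEALTH,
    _HL.SUB_HEALTH, _HL.HEALTHY, _HL.SUB_HEALTH, _HL.MORBID, _HL.UNHEALTHY,
    _HL.MORBID, _HL.UNHEALTHY, _HL.MORBID, _HL.UNHEALTHY,
]

# Published indicator names; direction assignment is editorial (see module
# docstring).
_NEGATIVE_IDS = {"Y_12", "Y_13", "Z_1", "Z_3", "Z_4"}
_INDICATOR_NAMES = {
    "X_1": "Gross marine product",
    "X_2": "Per capita gross marine product",
    "X_3": "Proportion of marine GDP in regional GDP",
    "X_4": "Proportion of marine secondary industry in marine GDP",
    "X_5": "Proportion of marine tertiary industry in marine GDP",
    "X_6": "Production quantity of offshore crude oil",
    "X_7": "Production quantity of offshore natural gas",
    "X_8": "Marine mining output",
    "X_9": "Output of sea salt",
    "X_10": "Output of marine chemical products",
    "X_11": "Cargo throughput of coastal ports",
    "X_12": "Ocean freight volume",
    "X_13": "Marine passenger volume",
    "Y_1": "Phytoplankton diversity index",
    "Y_2": "Macrozooplankton diversity index",
    "Y_3": "Benthic diversity index",
    "Y_4": "Area of marine nature reserve",
    "Y_5": "Offshore and coastal wetland area",
    "Y_6": "Mariculture area",
    "Y_7": "Proportion of natural reserve area",
    "Y_8": "Proportion of good days in bathing beach",
    "Y_9": "Area of marine ecological monitoring area",
    "Y_10": "Output of seawater products",
    "Y_11": "Number of domestic tourists in coastal cities",
    "Y_12": "Total amount of sewage discharged directly to the sea",
    "Y_13": "Total amount of pollutants directly discharged into the sea",
    "Z_1": "Population density",
    "Z_2": "Natural growth rate of population",
    "Z_3": "Proportion of class IV and inferior class IV seawater",
    "Z_4": "Average density of beach garbage in the monitoring area",
    "Z_5": "Total annual investment of pollution control projects",
    "Z_6": "Proportion of environmental protection investment in GDP",
    "Z_7": "Treatment capacity of industrial wastewater facilities",
    "Z_8": "Comprehensive utilization quantity of industrial solid waste",
    "Z_9": "Per capita disposable income of urban residents",
    "Z_10": "Per capita consumption of urban residents",
    "Z_11": "Number of medical and health institutions",
    "Z_12": "Number of health personnel",
    "Z_13": "Number of beds in medical and health institutions",
}


def shandong_definitions() -> tuple[IndicatorDefinition, ...]:
    """The 39-indicator evaluation system with the default direction set."""
    subsystem_of = {}
    for iid in _WEIGHTS_ECONOMIC:
        subsystem_of[iid] = Subsystem.ECONOMIC
    for iid in _WEIGHTS_ECOLOGICAL:
        subsystem_of[iid] = Subsystem.ECOLOGICAL
    for iid in _WEIGHTS_HUMAN:
        subsystem_of[iid] = Subsystem.HUMAN
    return tuple(
        IndicatorDefinition(
            id=iid,
            name=_INDICATOR_NAMES[iid],
            subsystem=subsystem_of[iid],
            direction=Direction.NEGATIVE if iid in _NEGATIVE_IDS else Direction.POSITIVE,
            units="",
        )
        for iid in subsystem_of
    )


@dataclass(frozen=True)
class ShandongFixture:
    """Printed Shandong results: weights, moduli, ideals and diagnosis."""

    years: Sequence[int]
    definitions: tuple[IndicatorDefinition, ...]
    weights: pd.Series  # indicator id -> published weight
    subsystem_moduli: pd.DataFrame  # year x subsystem modulus
    subsystem_ideals: Mapping[Subsystem, float]
    subsystem_types: pd.DataFrame  # year x subsystem printed carrying type
    ecc: pd.Series  # year -> overall modulus
    ecc_star: float
    ecc_types: Sequence[CarryingType]
    trends: Sequence[Trend | None]
    warning_levels: Sequence[WarningLevel]
    warning_degrees: Sequence[WarningDegree]
    health_levels: Sequence[HealthLevel]


def load_fixture_shandong() -> ShandongFixture:
    """Return the published Shandong tables exactly as printed."""
    weights = pd.Series({**_WEIGHTS_ECONOMIC, **_WEIGHTS_ECOLOGICAL, **_WEIGHTS_HUMAN})
    moduli = pd.DataFrame(
        {sub.value: vals for sub, vals in _SUBSYSTEM_MODULI.items()},
        index=pd.Index(YEARS, name="year"),
    )
    types = pd.DataFrame(
        {sub.value: vals for sub, vals in _SUBSYSTEM_TYPES.items()},
        index=pd.Index(YEARS, name="year"),
    )
    return ShandongFixture(
        years=tuple(YEARS),
        definitions=shandong_definitions(),
        weights=weights,
        subsystem_moduli=moduli,
        subsystem_ideals=dict(_SUBSYSTEM_IDEALS),
        subsystem_types=types,
        ecc=pd.Series(_ECC, index=pd.Index(YEARS, name="year")),
        ecc_star=_ECC_STAR,
        ecc_types=tuple(_ECC_TYPES),
        trends=tuple(_TRENDS),
        warning_levels=tuple(_WARNING_LEVELS),
        warning_degrees=tuple(_WARNING_DEGREES),
        health_levels=tuple(_HEALTH_LEVELS),
    )
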