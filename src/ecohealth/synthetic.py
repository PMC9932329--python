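"""Synthetic indicator panels and engineered diagnosis scenarios.

Two generators:

* :func:`generate_panel` draws a realistic-shaped raw panel — per
  indicator a positive baseline with a linear drift and Gaussian noise,
  optional missingness — mirroring the 3-subsystem x 13-indicator x
  13-year shape of the motivating study. It is a test harness, not a
  model of any real coastal zone's marginal distributions.

* :func:`generate_scenario` inverts the diagnosis chain: given a target
  carrying-type trajectory it constructs a panel of already-normalized
  values (one indicator per subsystem, weight one) whose yearly overall
  modulus sits at the midpoint of each demanded band relative to a fixed
  ideal modulus, along with the diagnosis records the pipeline must
  reproduce. Band midpoints keep the construction clear of the
  boundary-inclusivity edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnosis import BandScheme, assess_trend, health_level, warning_level
from .state_space import assess
from .types import (
    CarryingType,
    DiagnosisRecord,
    Direction,
    IndicatorDefinition,
    IndicatorPanel,
    NormalizedPanel,
    PipelineConfig,
    Subsystem,
    Trend,
    WeightVector,
)

__all__ = ["ScenarioSpec", "generate_panel", "generate_scenario"]

_SUB_PREFIX = {
    Subsystem.ECONOMIC: "X",
    Subsystem.ECOLOGICAL: "Y",
    Subsystem.HUMAN: "Z",
}


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic panel.

    Defaults emulate the motivating study's panel: 13 annual
    observations of 3 subsystems x 13 indicators, a small negative-
    direction minority (5 of 39, as in the shipped default direction
    set), mild growth trends with ~5% relative noise, and a low
    missingness rate ("a small number of missing data").
    """

    n_years: int = 13
    per_subsystem: int = 13
    start_year: int = 2007
    n_negative_per_subsystem: int = 2  # ~5/39 overall in the emulated system
    baseline: float = 100.0
    drift_scale: float = 0.05  # max |drift| per year, relative to baseline
    noise_scale: float = 0.05  # noise sd relative to baseline
    missing_rate: float = 0.02
    seed: int = 0
    target_trajectory: Sequence[CarryingType] | None = None
    scenario_ecc_star: float = 0.5

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("need at least two years")
        if self.per_subsystem < 1:
            raise ValueError("need at least one indicator per subsystem")
        if not (0 <= self.missing_rate <= 0.5):
            raise ValueError("missingness rate must lie in [0, 0.5]")
        if self.n_negative_per_subsystem > self.per_subsystem:
            raise ValueError("more negative indicators than indicators")


def _definitions(spec: ScenarioSpec) -> tuple[IndicatorDefinition, ...]:
    defs = []
    for sub, prefix in _SUB_PREFIX.items():
        for i in range(1, spec.per_subsystem + 1):
            direction = (
                Direction.NEGATIVE
                if i <= spec.n_negative_per_subsystem
                else Direction.POSITIVE
            )
            defs.append(
                IndicatorDefinition(
                    id=f"{prefix}_{i}",
                    name=f"synthetic {sub.value} indicator {i}",
                    subsystem=sub,
                    direction=direction,
                    units="arbitrary",
                )
            )
    return tuple(defs)


def generate_panel(spec: ScenarioSpec) -> tuple[IndicatorPanel, tuple[IndicatorDefinition, ...]]:
    """Draw a raw panel: baseline + drift * t + Gaussian noise, floored
    at a positive minimum; missing cells uniform at the stated rate but
    never in a column's first year. Identical seeds give identical panels."""
    rng = np.random.default_rng(spec.seed)
    defs = _definitions(spec)
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    t = np.arange(spec.n_years, dtype=float)

    columns = {}
    for d in defs:
        base = spec.baseline * rng.uniform(0.5, 1.5)
        drift = rng.uniform(-spec.drift_scale, spec.drift_scale) * base
        noise = rng.normal(0.0, spec.noise_scale * base, size=spec.n_years)
        x = base + drift * t + noise
        columns[d.id] = np.maximum(x, 0.01 * base)  # positive floor

    values = pd.DataFrame(columns, index=pd.Index(years, name="year"))
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        mask[0, :] = False  # first year always observed
        values = values.mask(mask)
    return IndicatorPanel(values=values, definitions=defs), defs


def _expected_records(
    years: Sequence[int],
    ecc_values: Sequence[float],
    ecc_star: float,
    config: PipelineConfig,
) -> list[DiagnosisRecord]:
    scheme = BandScheme(config.band_multipliers)
    records = []
    prev: float | None = None
    for year, value in zip(years, ecc_values):
        ctype = scheme.classify(value, ecc_star)
        trend = assess_trend(value, prev, config.trend_tie_rule, config.first_year_rule)
        level, degree = warning_level(ctype, trend)
        records.append(
            DiagnosisRecord(
                year=int(year),
                carrying_type=ctype,
                trend=trend,
                warning_level=level,
                warning_degree=degree,
                health_level=health_level(degree),
            )
        )
        prev = value
    return records


def generate_scenario(
    spec: ScenarioSpec, config: PipelineConfig | None = None
) -> tuple[NormalizedPanel, WeightVector, dict[str, float], list[DiagnosisRecord]]:
    """Construct a normalized panel realizing a target band trajectory.

    Returns (normalized panel, unit weights, fixed ideal values, expected
    records). One positive indicator per subsystem carries weight one;
    each year the three indicators share the value that puts the overall
    modulus at the midpoint of the demanded band times the fixed ideal
    modulus. Running the scoring and diagnosis chain on the returned
    panel (ideal strategy "fixed") must reproduce the expected records.
    """
    if spec.target_trajectory is None:
        raise ValueError("spec has no target trajectory")
    if len(spec.target_trajectory) != spec.n_years:
        raise ValueError("trajectory length must match the number of years")
    config = config or PipelineConfig()
    scheme = BandScheme(config.band_multipliers)
    ecc_star = spec.scenario_ecc_star

    defs = tuple(
        IndicatorDefinition(
            id=f"{prefix}_1",
            name=f"scenario {sub.value} indicator",
            subsystem=sub,
            direction=Direction.POSITIVE,
            units="normalized",
        )
        for sub, prefix in _SUB_PREFIX.items()
    )
    years = list(range(spec.start_year, spec.start_year + spec.n_years))

    per_year_value = []
    for band in spec.target_trajectory:
        target_ecc = scheme.midpoint_ratio(CarryingType(band)) * ecc_star
        v = target_ecc / np.sqrt(3.0)
        if not (0.0 <= v <= 1.0):
            raise ValueError(
                f"infeasible trajectory: band {band} needs a normalized value of "
                f"{v:.3f} outside [0, 1] at ideal modulus {ecc_star}"
            )
        per_year_value.append(v)

    values = pd.DataFrame(
        {d.id: per_year_value for d in defs}, index=pd.Index(years, name="year")
    )
    panel = NormalizedPanel(values=values, definitions=defs)
    weights = WeightVector(
        weights=pd.Series(1.0, index=values.columns),
        subsystems=panel.subsystem_of(),
    )
    ideal_value = ecc_star / np.sqrt(3.0)
    if ideal_value > 1.0:
        raise ValueError("infeasible scenario: ideal modulus exceeds sqrt(3)")
    fixed_ideals = {d.id: ideal_value for d in defs}

    ecc_values = [float(np.sqrt(3.0) * v) for v in per_year_value]
    expected = _expected_records(years, ecc_values, ecc_star, config)
    return panel, weights, fixed_ideals, expected
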