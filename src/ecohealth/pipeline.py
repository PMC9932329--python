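"""End-to-end orchestration: raw panel in, assessment and diagnosis out."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diagnosis import diagnose_series, subsystem_diagnosis
from .preprocessing import ColumnStats, compute_weights, impute_missing, normalize
from .state_space import (
    IndicatorLoads,
    assess,
    compute_loads,
    contribution_rates,
    subsystem_shares,
)
from .types import (
    CarryingAssessment,
    DiagnosisRecord,
    IndicatorPanel,
    NormalizedPanel,
    PipelineConfig,
    Subsystem,
    WeightVector,
)

logger = logging.getLogger("ecohealth")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline computes, stage by stage."""

    panel: IndicatorPanel  # complete (imputed) raw panel
    normalized: NormalizedPanel
    weights: WeightVector
    stats: ColumnStats
    loads: IndicatorLoads
    assessment: CarryingAssessment
    records: list[DiagnosisRecord]
    subsystem_table: pd.DataFrame
    contributions: pd.DataFrame
    shares: dict[Subsystem, float]


def run_pipeline(
    panel: IndicatorPanel,
    config: PipelineConfig | None = None,
    weights: WeightVector | None = None,
) -> PipelineResult:
    """Impute, weight, normalize, score and diagnose a raw panel.

    ``weights`` overrides the coefficient-of-variation weighting with a
    user-supplied vector (already validated to sum to one per subsystem).
    """
    config = config or PipelineConfig()

    logger.info("imputing missing values (alpha=%.2f)", config.smoothing_alpha)
    complete = impute_missing(panel, alpha=config.smoothing_alpha)

    logger.info("computing coefficient-of-variation weights (basis=%s)", config.cv_basis)
    cv_weights, stats = compute_weights(complete, basis=config.cv_basis)
    if weights is None:
        weights = cv_weights

    logger.info("range-normalizing %d indicators", len(complete.indicator_ids))
    normalized = normalize(complete)

    logger.info("scoring carrying capacity (ideal strategy=%s)", config.ideal_strategy)
    assessment = assess(
        normalized,
        weights,
        strategy=config.ideal_strategy,
        fixed_values=config.fixed_ideal_values,
    )
    loads = compute_loads(normalized, weights)

    logger.info("running the diagnosis chain over %d years", len(assessment.years))
    records = diagnose_series(assessment, config)
    subsystem_table = subsystem_diagnosis(assessment, config)
    contributions = contribution_rates(loads, definition=config.contribution_definition)
    shares = subsystem_shares(assessment)

    return PipelineResult(
        panel=complete,
        normalized=normalized,
        weights=weights,
        stats=stats,
        loads=loads,
        assessment=assessment,
        records=records,
        subsystem_table=subsystem_table,
        contributions=contributions,
        shares=shares,
    )
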