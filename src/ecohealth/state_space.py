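"""State-space carrying-capacity scoring.

A year's system state is the vector of per-indicator loads
w_i * Y_i (weight times normalized value); the carrying capacity is its
Euclidean modulus, computed per subsystem and overall:

    ECC = sqrt( sum_ec (w_i E_i)^2 + sum_es (w_j R_j)^2 + sum_ha (w_k H_k)^2 )

The ideal state ECC* is the modulus of a reference vector — by default
the per-indicator mean of the normalized panel over the study period —
and yearly moduli are judged against bands of ECC* downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    CarryingAssessment,
    NormalizedPanel,
    Subsystem,
    WeightVector,
)

__all__ = [
    "IndicatorLoads",
    "IdealState",
    "compute_loads",
    "subsystem_modulus",
    "overall_modulus",
    "ideal_state",
    "assess",
    "contribution_rates",
    "subsystem_shares",
]


@dataclass
class IndicatorLoads:
    """Per-year, per-indicator loads w * Y with their subsystem grouping."""

    values: pd.DataFrame  # year x indicator id
    subsystems: pd.Series  # indicator id -> Subsystem

    def __post_init__(self) -> None:
        if (self.values < 0).to_numpy().any():
            raise ValueError("loads must be nonnegative")

    def for_subsystem(self, subsystem: Subsystem) -> pd.DataFrame:
        cols = self.subsystems[self.subsystems == subsystem].index
        return self.values[cols]


@dataclass(frozen=True)
class IdealState:
    """Ideal normalized values and the moduli they induce."""

    ideal_values: pd.Series  # indicator id -> ideal normalized value
    ideal_loads: pd.Series  # indicator id -> weight * ideal value
    subsystem_moduli: Mapping[Subsystem, float]
    modulus: float
    strategy: str


def compute_loads(norm: NormalizedPanel, weights: WeightVector) -> IndicatorLoads:
    """Loads w_i * Y_i for every year and indicator."""
    missing = [c for c in norm.values.columns if c not in weights.weights.index]
    if missing:
        raise ValueError(f"no weights for indicators: {missing}")
    loads = norm.values * weights.weights[norm.values.columns]
    return IndicatorLoads(values=loads, subsystems=norm.subsystem_of())


def subsystem_modulus(loads: np.ndarray | pd.Series) -> float:
    """Root-sum-of-squares of one subsystem's loads for one year."""
    arr = np.asarray(loads, dtype=float)
    if (arr < 0).any():
        raise ValueError("loads must be nonnegative")
    return float(np.sqrt((arr**2).sum()))


def overall_modulus(ecc_ec: float, ecc_es: float, ecc_ha: float) -> float:
    """Overall modulus from the three subsystem moduli (Pythagorean)."""
    if min(ecc_ec, ecc_es, ecc_ha) < 0:
        raise ValueError("subsystem moduli must be nonnegative")
    return float(np.sqrt(ecc_ec**2 + ecc_es**2 + ecc_ha**2))


def ideal_state(
    norm: NormalizedPanel,
    weights: WeightVector,
    strategy: str = "mean",
    fixed_values: Mapping[str, float] | None = None,
) -> IdealState:
    """Reference ("ideal") state against which yearly moduli are banded.

    strategy "mean" takes each indicator's ideal value as its mean
    normalized value over the study period; "max" takes the column
    maximum (i.e. ideal = best observed); "fixed" uses supplied values
    in [0, 1].
    """
    cols = norm.values.columns
    if strategy == "mean":
        ideal = norm.values.mean(axis=0)
    elif strategy == "max":
        ideal = norm.values.max(axis=0)
    elif strategy == "fixed":
        if fixed_values is None:
            raise ValueError("strategy 'fixed' requires fixed ideal values")
        absent = [c for c in cols if c not in fixed_values]
        if absent:
            raise ValueError(f"fixed ideal values missing indicators: {absent}")
        ideal = pd.Series({c: float(fixed_values[c]) for c in cols})
        if ((ideal < 0) | (ideal > 1)).any():
            raise ValueError("fixed ideal values must lie in [0, 1]")
    else:
        raise ValueError(f"unknown ideal strategy: {strategy!r}")

    ideal = ideal.reindex(cols)
    ideal_loads = ideal * weights.weights[cols]
    subsystems = norm.subsystem_of()
    sub_moduli = {
        sub: subsystem_modulus(ideal_loads[subsystems[subsystems == sub].index])
        for sub in Subsystem
    }
    return IdealState(
        ideal_values=ideal,
        ideal_loads=ideal_loads,
        subsystem_moduli=sub_moduli,
        modulus=overall_modulus(*(sub_moduli[s] for s in Subsystem)),
        strategy=strategy,
    )


def assess(
    norm: NormalizedPanel,
    weights: WeightVector,
    strategy: str = "mean",
    fixed_values: Mapping[str, float] | None = None,
) -> CarryingAssessment:
    """Yearly subsystem and overall moduli plus the ideal-state moduli."""
    loads = compute_loads(norm, weights)
    ideal = ideal_state(norm, weights, strategy=strategy, fixed_values=fixed_values)
    rows = {}
    for sub, col in CarryingAssessment.SUB_COLUMNS.items():
        sub_loads = loads.for_subsystem(sub)
        rows[col] = np.sqrt((sub_loads.to_numpy() ** 2).sum(axis=1))
    moduli = pd.DataFrame(rows, index=norm.values.index)
    moduli["ecc"] = np.sqrt((moduli.to_numpy() ** 2).sum(axis=1))
    ideal_row = {
        col: ideal.subsystem_moduli[sub] for sub, col in CarryingAssessment.SUB_COLUMNS.items()
    }
    ideal_row["ecc"] = ideal.modulus
    return CarryingAssessment(moduli=moduli, ideal=ideal_row, ideal_strategy=strategy)


def contribution_rates(loads: IndicatorLoads, definition: str = "linear") -> pd.DataFrame:
    """Percentage contribution of each indicator to its subsystem.

    Each indicator's carrying contribution is its load averaged over
    years; under the linear definition (default) the share denominator is
    the sum of same-subsystem mean loads, so percentages sum to 100 per
    subsystem. The squared definition uses mean squared loads instead.
    """
    if definition not in {"linear", "squared"}:
        raise ValueError(f"unknown contribution definition: {definition!r}")
    base = loads.values**2 if definition == "squared" else loads.values
    mean_loads = base.mean(axis=0)
    out = []
    for sub in Subsystem:
        cols = loads.subsystems[loads.subsystems == sub].index
        if len(cols) == 0:
            continue
        total = mean_loads[cols].sum()
        if total == 0:
            raise ValueError(f"subsystem {sub.value!r} has all-zero loads")
        for c in cols:
            out.append(
                {
                    "indicator": c,
                    "subsystem": sub.value,
                    "contribution_pct": 100.0 * mean_loads[c] / total,
                }
            )
    return pd.DataFrame(out).set_index("indicator")


def subsystem_shares(assessment: CarryingAssessment) -> dict[Subsystem, float]:
    """Average percentage share of each subsystem in the yearly linear sum.

    For each year, share_sub = ECC_sub / (ECC_ec + ECC_es + ECC_ha); the
    shares are averaged over years and reported as percentages.
    """
    cols = CarryingAssessment.SUB_COLUMNS
    sub = assessment.moduli[list(cols.values())]
    totals = sub.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero subsystem moduli in years: {bad}")
    shares = sub.div(totals, axis=0).mean(axis=0) * 100.0
    return {s: float(shares[c]) for s, c in cols.items()}
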