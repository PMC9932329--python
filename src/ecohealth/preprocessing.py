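"""Panel preprocessing: imputation, range normalization, CV weighting.

Three stages stand between a raw indicator panel and the state-space
scoring:

1. Missing observations are filled by simple exponential smoothing over
   each column's observed values in year order.
2. Each column is range (min-max) normalized into [0, 1], mirrored for
   negative-direction indicators so that 1 always means "loads the
   system most".
3. Objective weights come from the coefficient of variation of each
   column, renormalized to sum to one within each subsystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    Direction,
    IndicatorPanel,
    NormalizedPanel,
    Subsystem,
    WeightVector,
)

logger = logging.getLogger("ecohealth")

__all__ = ["ColumnStats", "impute_missing", "normalize", "compute_weights"]


@dataclass(frozen=True)
class ColumnStats:
    """Per-indicator summary statistics underlying the CV weights.

    ``std`` is the population standard deviation (divisor n); ``cv`` is
    std / |mean|.
    """

    table: pd.DataFrame  # indexed by indicator id: min, max, mean, std, cv


def impute_missing(panel: IndicatorPanel, alpha: float = 0.5) -> IndicatorPanel:
    """Fill missing cells by simple exponential smoothing per column.

    The smoothing state starts at the first observed value (s1 = x1) and
    updates as s_t = alpha*x_t + (1-alpha)*s_{t-1} over observed values in
    year order. A missing cell is filled with the state carried from the
    most recent preceding observation; cells before the first observation
    are back-filled with the first observed value. With alpha = 1 this is
    last-observation-carried-forward.
    """
    if not (0 < alpha <= 1):
        raise ValueError("smoothing coefficient must be in (0, 1]")
    values = panel.values.copy()
    for col in values.columns:
        x = values[col].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        if not obs.any():
            raise ValueError(f"indicator {col!r} has no observed values")
        first = int(np.argmax(obs))
        state = x[first]
        filled = x.copy()
        filled[:first] = state  # back-fill before the first observation
        for t in range(first, len(x)):
            if obs[t]:
                state = alpha * x[t] + (1 - alpha) * state if t > first else x[t]
            else:
                filled[t] = state
        values[col] = filled
    return panel.with_values(values)


def normalize(panel: IndicatorPanel) -> NormalizedPanel:
    """Range-normalize each column into [0, 1] over the panel's full span.

    Positive indicators map min -> 0 and max -> 1; negative indicators are
    mirrored (min -> 1, max -> 0). A constant column is degenerate for the
    range transform; it is set to 0.5 with a warning — the CV weighting
    assigns it weight zero, so it cannot influence any modulus.
    """
    if not panel.is_complete:
        raise ValueError("panel must be complete (impute first)")
    directions = {d.id: d.direction for d in panel.definitions}
    out = {}
    for col in panel.values.columns:
        x = panel.values[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning("indicator %r is constant; normalized to 0.5", col)
            out[col] = np.full_like(x, 0.5)
            continue
        y = (x - lo) / (hi - lo)
        if directions[col] is Direction.NEGATIVE:
            y = 1.0 - y
        out[col] = y
    values = pd.DataFrame(out, index=panel.values.index)
    return NormalizedPanel(values=values, definitions=panel.definitions)


def compute_weights(
    panel: IndicatorPanel, basis: str = "raw"
) -> tuple[WeightVector, ColumnStats]:
    """Coefficient-of-variation weights, normalized within each subsystem.

    For each column, V = sigma / |mean| with the population sigma
    (divisor n); within each subsystem the weight of column i is
    V_i / sum(V). A zero-variance column gets weight 0. ``basis`` selects
    whether the CV is taken on the raw panel (default, per the published
    procedure) or on normalized values.
    """
    if basis not in {"raw", "normalized"}:
        raise ValueError(f"unknown CV basis: {basis!r}")
    if not panel.is_complete:
        raise ValueError("panel must be complete (impute first)")
    data = normalize(panel).values if basis == "normalized" else panel.values

    stats = {}
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        mean = x.mean()
        # an exactly-constant column is zero-variance even when the float
        # mean subtraction leaves ulp-level residue
        std = 0.0 if x.max() == x.min() else x.std(ddof=0)
        if std > 0 and mean == 0:
            raise ValueError(
                f"indicator {col!r} has zero mean; coefficient of variation undefined"
            )
        cv = 0.0 if std == 0 else std / abs(mean)
        stats[col] = {"min": x.min(), "max": x.max(), "mean": mean, "std": std, "cv": cv}
    table = pd.DataFrame(stats).T.reindex(data.columns)

    subsystems = panel.subsystem_of()
    weights = pd.Series(0.0, index=data.columns)
    for sub in Subsystem:
        cols = subsystems[subsystems == sub].index
        if len(cols) == 0:
            continue
        v = table.loc[cols, "cv"]
        total = v.sum()
        if total == 0:
            raise ValueError(
                f"all indicators of subsystem {sub.value!r} have zero variance"
            )
        weights[cols] = v / total
    return WeightVector(weights=weights, subsystems=subsystems), ColumnStats(table=table)
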