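"""Readers and writers for indicator panels, metadata, configs and reports.

File conventions: UTF-8, comma-delimited, header row, blank cell = missing
observation. Panels have a leading ``year`` column; metadata files carry
``id,name,subsystem,direction,units``.
"""

from __future__ import annotations

import decimal
import logging
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
import yaml

from .types import (
    CarryingAssessment,
    DiagnosisRecord,
    Direction,
    IndicatorDefinition,
    IndicatorPanel,
    PipelineConfig,
    Subsystem,
    CarryingType,
    Trend,
)

logger = logging.getLogger("ecohealth")

_META_COLUMNS = ["id", "name", "subsystem", "direction", "units"]


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal half-up rounding for display (0.0915 -> 0.092 at 3 dp)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def parse_metadata(source: str | Path | IO[str]) -> tuple[IndicatorDefinition, ...]:
    """Read indicator definitions from delimited text.

    Rejects duplicate ids and unknown subsystem/direction values.
    An empty data section yields an empty tuple.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    definitions: list[IndicatorDefinition] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        iid = row["id"].strip()
        if iid in seen:
            raise ValueError(f"duplicate indicator id: {iid!r}")
        seen.add(iid)
        try:
            subsystem = Subsystem(row["subsystem"].strip())
        except ValueError:
            raise ValueError(
                f"indicator {iid!r}: unknown subsystem {row['subsystem']!r} "
                f"(expected one of {[s.value for s in Subsystem]})"
            ) from None
        try:
            direction = Direction(row["direction"].strip())
        except ValueError:
            raise ValueError(
                f"indicator {iid!r}: unknown direction {row['direction']!r}"
            ) from None
        definitions.append(
            IndicatorDefinition(
                id=iid,
                name=row["name"].strip(),
                subsystem=subsystem,
                direction=direction,
                units=row["units"].strip(),
            )
        )
    return tuple(definitions)


def parse_panel(
    source: str | Path | IO[str], definitions: Sequence[IndicatorDefinition]
) -> IndicatorPanel:
    """Read a year x indicator panel; blank cells become missing values."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if df.columns[0] != "year":
        raise ValueError(f"first panel column must be 'year', got {df.columns[0]!r}")
    known = {d.id for d in definitions}
    unknown = [c for c in df.columns[1:] if c not in known]
    if unknown:
        raise ValueError(f"panel columns without metadata: {unknown}")
    try:
        years = df["year"].astype(int)
    except ValueError as exc:
        raise ValueError(f"non-integer year value: {exc}") from None
    values = df.drop(columns="year")
    for col in values.columns:
        # Python's float() parses round-trip exactly; blank means missing
        def cell(s: str) -> float:
            if s == "":
                return float("nan")
            try:
                return float(s)
            except ValueError:
                raise ValueError(f"non-numeric cell in column {col!r}: {s!r}") from None

        values[col] = values[col].map(cell)
    values.index = pd.Index(years, name="year")
    used = [d for d in definitions if d.id in values.columns]
    return IndicatorPanel(values=values.astype(float), definitions=used)


def write_metadata(definitions: Iterable[IndicatorDefinition], path: str | Path) -> None:
    rows = [
        {
            "id": d.id,
            "name": d.name,
            "subsystem": d.subsystem.value,
            "direction": d.direction.value,
            "units": d.units,
        }
        for d in definitions
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def write_panel(panel: IndicatorPanel, path: str | Path) -> None:
    """Write a panel as CSV; missing cells are written blank.

    Full float precision is preserved so a write/parse round trip is exact.
    """
    out = panel.values.copy()
    out.insert(0, "year", panel.years)
    out.to_csv(path, index=False, na_rep="", float_format=lambda v: repr(float(v)))


def load_config(source: str | Path | IO[str]) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key-value file."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        raw = yaml.safe_load(Path(source).read_text())
    raw = raw or {}
    if "band_multipliers" in raw:
        raw["band_multipliers"] = tuple(raw["band_multipliers"])
    return PipelineConfig(**raw)


def _format_trend(record: DiagnosisRecord) -> str:
    # Green years and severe overload carry no arrow in printed reports.
    if record.warning_level.value == "green":
        return "—"
    if record.carrying_type is CarryingType.SEVERE_OVERLOAD:
        return "—"
    return "↗" if record.trend is Trend.AGGRAVATED else "↘"


def diagnosis_frame(records: Sequence[DiagnosisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [r.year for r in records],
            "carrying_type": [r.carrying_type.value for r in records],
            "trend": [r.trend.value for r in records],
            "warning_level": [r.warning_level.value for r in records],
            "warning_degree": [r.warning_degree.value for r in records],
            "health_level": [r.health_level.value for r in records],
        }
    ).set_index("year")


def write_diagnosis_report(
    assessment: CarryingAssessment,
    records: Sequence[DiagnosisRecord],
    destination: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Write the assessment and diagnosis tables plus a readable summary.

    Produces ``assessment.csv`` (yearly moduli, display-rounded),
    ``diagnosis.csv`` (the machine-readable chain output) and
    ``report.md``. Classification upstream always uses unrounded values;
    rounding here is presentation only.
    """
    config = config or PipelineConfig()
    record_years = [r.year for r in records]
    if record_years != assessment.years:
        raise ValueError(
            f"records cover years {record_years} but assessment covers {assessment.years}"
        )
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    nd = config.report_decimals

    rounded = assessment.moduli.map(lambda v: round_half_up(v, nd))
    rounded.index.name = "year"
    assessment_path = dest / "assessment.csv"
    with open(assessment_path, "w", encoding="utf-8") as fh:
        fh.write(f"# ideal_strategy: {assessment.ideal_strategy}\n")
        for key in ("ecc_economic", "ecc_ecological", "ecc_human", "ecc"):
            fh.write(f"# ideal_{key}: {round_half_up(assessment.ideal[key], nd + 1)}\n")
        rounded.to_csv(fh)

    diag = diagnosis_frame(records)
    diagnosis_path = dest / "diagnosis.csv"
    diag.to_csv(diagnosis_path)

    report_path = dest / "report.md"
    lines = [
        "# Coastal ecosystem health diagnosis",
        "",
        f"Years: {assessment.years[0]}–{assessment.years[-1]}  ",
        f"Ideal-state modulus ECC* = {round_half_up(assessment.ecc_star, nd + 1)} "
        f"(strategy: {assessment.ideal_strategy})",
        "",
        "| Year | ECC | Carrying type | Trend | Warning | Degree | Health |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in records:
        ecc = round_half_up(float(assessment.ecc.loc[r.year]), nd)
        lines.append(
            f"| {r.year} | {ecc:.{nd}f} | {r.carrying_type} | {_format_trend(r)} "
            f"| {r.warning_level} | {r.warning_degree} | {r.health_level} |"
        )
    report_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    logger.info("wrote diagnosis report to %s", dest)
    return {"assessment": assessment_path, "diagnosis": diagnosis_path, "report": report_path}
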