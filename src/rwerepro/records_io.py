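"""Data model and delimited-file I/O for paired original/reproduction study records.

Three UTF-8 comma-separated tables with required headers make up a portfolio:

* ``studies.csv`` — one row per study *arm*; study-level fields (design,
  effect estimates, attributes) are repeated on every arm row and must agree.
  The reference arm is listed last and flagged by ``is_reference``.
* ``covariates.csv`` — one row per study x covariate x arm with original and
  reproduction prevalences in percent.
* ``checklist.csv`` — one row per study with 54 item responses and
  per-category assumption flags (see :mod:`rwerepro.reporting_clarity`).

Absent numeric values are written as empty strings, never 0 — absence is
meaningful (many publications omit p-values).  Effect estimates are stored on
the ratio scale; logs are taken at computation time only.  One CSV dialect is
used, with a period decimal separator regardless of locale.

Readers validate every row: each input row ends either in the record list or
in the rejection report, never silently dropped.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

__all__ = [
    "Measure",
    "Design",
    "EffectEstimate",
    "ArmResult",
    "StudyResult",
    "StudyPair",
    "CovariateEntry",
    "Rejection",
    "TableReadResult",
    "SchemaError",
    "STUDY_COLUMNS",
    "COVARIATE_COLUMNS",
    "read_study_pairs",
    "write_study_pairs",
    "read_covariates",
    "write_covariates",
    "read_checklist",
    "write_checklist",
    "load_column_map",
]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """Header/column-dictionary mismatch (names the offending column)."""


class Measure(str, enum.Enum):
    HR = "HR"
    RR = "RR"
    OR = "OR"


class Design(str, enum.Enum):
    comparative = "comparative"
    descriptive = "descriptive"


class EffectEstimate(BaseModel):
    """A ratio-scale measure of association (HR/RR/OR) with optional CI and p."""

    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    measure: Measure = Measure.HR

    @model_validator(mode="after")
    def _check(self) -> "EffectEstimate":
        if not (self.point > 0) or not math.isfinite(self.point):
            raise ValueError(f"effect point must be a positive real, got {self.point}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not (0 < self.ci_low <= self.point <= self.ci_high):
                raise ValueError(
                    f"CI invariant violated: need 0 < ci_low <= point <= ci_high, "
                    f"got ({self.ci_low}, {self.point}, {self.ci_high})"
                )
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")
        return self

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None

    @property
    def log_point(self) -> float:
        return math.log(self.point)


class ArmResult(BaseModel):
    """Cohort-level results for one exposure arm (or the whole descriptive cohort)."""

    arm_id: str
    n: int = Field(ge=0)
    events: Optional[int] = Field(default=None, ge=0)
    risk_pct: Optional[float] = None
    rate_per100py: Optional[float] = None
    person_years: Optional[float] = None
    is_reference: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ArmResult":
        if self.events is not None and self.events > self.n:
            raise ValueError(f"events ({self.events}) exceed n ({self.n})")
        if self.risk_pct is not None and not (0.0 <= self.risk_pct <= 100.0):
            raise ValueError(f"risk_pct must lie in [0, 100], got {self.risk_pct}")
        if self.rate_per100py is not None and self.rate_per100py < 0:
            raise ValueError("rate_per100py must be nonnegative")
        if self.person_years is not None and self.person_years < 0:
            raise ValueError("person_years must be nonnegative")
        if (
            self.events is not None
            and self.person_years
            and self.rate_per100py is not None
        ):
            implied = 100.0 * self.events / self.person_years
            if implied > 0 and abs(self.rate_per100py - implied) > 0.005 * implied:
                raise ValueError(
                    f"rate_per100py {self.rate_per100py} inconsistent with "
                    f"100*events/person_years = {implied:.4f} (0.5% tolerance)"
                )
        return self


class StudyResult(BaseModel):
    """One side (original or reproduction) of a study: arms plus optional effect."""

    arms: list[ArmResult] = Field(min_length=1)
    effect: Optional[EffectEstimate] = None

    @property
    def total_n(self) -> int:
        """Sample size as the sum over compared exposure groups."""
        return sum(a.n for a in self.arms)


class StudyPair(BaseModel):
    """One reproduced study: design label plus original and reproduction results."""

    study_id: str
    design: Design
    original: StudyResult
    reproduction: StudyResult
    attributes: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "StudyPair":
        if len(self.original.arms) != len(self.reproduction.arms):
            raise ValueError(
                f"arm count mismatch: original {len(self.original.arms)} vs "
                f"reproduction {len(self.reproduction.arms)}"
            )
        if self.design is Design.comparative:
            if len(self.original.arms) < 2:
                raise ValueError("comparative studies need >= 2 arms")
            if self.original.effect is None or self.reproduction.effect is None:
                raise ValueError("comparative studies need an effect on both sides")
        else:
            if self.original.effect is not None or self.reproduction.effect is not None:
                raise ValueError("descriptive studies carry no measure of association")
        return self


class CovariateEntry(BaseModel):
    study_id: str
    covariate: str
    arm_id: str
    prev_original_pct: float
    prev_reproduction_pct: float

    @model_validator(mode="after")
    def _check(self) -> "CovariateEntry":
        for name in ("prev_original_pct", "prev_reproduction_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        return self


@dataclass(frozen=True)
class Rejection:
    """One rejected input row with the reason it failed validation."""

    row_number: int  # 1-based data-row index (header excluded)
    study_id: str
    message: str


@dataclass
class TableReadResult:
    """Validated records plus the rejection report; counts sum to input rows."""

    records: list
    rejections: list[Rejection] = field(default_factory=list)
    n_input_rows: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# --- column dictionaries ----------------------------------------------------

ATTRIBUTE_COLUMNS = [
    "funding_source",
    "data_source",
    "publication_year",
    "journal_impact_band",
    "author_responsive",
    "same_group",
]

STUDY_COLUMNS = [
    "study_id",
    "design",
    "measure",
    "arm_id",
    "is_reference",
    "original_n",
    "original_events",
    "original_risk_pct",
    "original_rate_per100py",
    "original_person_years",
    "reproduction_n",
    "reproduction_events",
    "reproduction_risk_pct",
    "reproduction_rate_per100py",
    "reproduction_person_years",
    "original_effect",
    "original_ci_low",
    "original_ci_high",
    "original_p_value",
    "reproduction_effect",
    "reproduction_ci_low",
    "reproduction_ci_high",
    "reproduction_p_value",
] + ATTRIBUTE_COLUMNS

COVARIATE_COLUMNS = [
    "study_id",
    "covariate",
    "arm_id",
    "prev_original_pct",
    "prev_reproduction_pct",
]


def _fmt(value) -> str:
    """Locale-independent cell formatting; floats use shortest round-trip repr."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def _parse_float(cell: str) -> Optional[float]:
    return None if cell == "" else float(cell)


def _parse_int(cell: str) -> Optional[int]:
    return None if cell == "" else int(cell)


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in {"true", "1", "yes"}


def load_column_map(path) -> dict:
    """Load a YAML mapping file adapting foreign column names/units.

    Structure::

        columns: {source_name: canonical_name, ...}
        rate_unit: per_100py | per_1000py | per_py

    ``rate_unit`` declares the unit of the source rate columns; rates are
    rescaled to per-100-person-years on read.
    """
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh) or {}
    unit = mapping.get("rate_unit", "per_100py")
    factors = {"per_100py": 1.0, "per_1000py": 0.1, "per_py": 100.0}
    if unit not in factors:
        raise SchemaError(f"unknown rate_unit {unit!r}")
    mapping["_rate_factor"] = factors[unit]
    return mapping


def _open_table(path, columns: Sequence[str], column_map: Optional[dict]):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SchemaError("empty file: missing header")
    header = rows[0]
    if column_map:
        renames = column_map.get("columns", {})
        header = [renames.get(h, h) for h in header]
    missing = [c for c in columns if c not in header]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in columns}
    out = []
    for row in rows[1:]:
        out.append({c: (row[i] if i < len(row) else "") for c, i in idx.items()})
    return out


def _check_schema_version(schema_version: str) -> None:
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {schema_version!r} (supported: {SCHEMA_VERSION!r})"
        )


def read_study_pairs(
    path,
    schema_version: str = SCHEMA_VERSION,
    column_map: Optional[dict] = None,
) -> TableReadResult:
    """Read and validate studies.csv into :class:`StudyPair` records.

    Rows are grouped by ``study_id`` (rows of one study must be contiguous).
    Malformed studies go to the rejection report with the violated invariant.
    """
    _check_schema_version(schema_version)
    raw = _open_table(path, STUDY_COLUMNS, column_map)
    factor = (column_map or {}).get("_rate_factor", 1.0)

    groups: list[tuple[str, list[tuple[int, dict]]]] = []
    for i, row in enumerate(raw, start=1):
        sid = row["study_id"]
        if groups and groups[-1][0] == sid:
            groups[-1][1].append((i, row))
        else:
            groups.append((sid, [(i, row)]))

    records: list[StudyPair] = []
    rejections: list[Rejection] = []
    for sid, rows in groups:
        try:
            records.append(_build_pair(sid, [r for _, r in rows], factor))
        except (ValidationError, ValueError) as exc:
            rejections.append(Rejection(rows[0][0], sid, _short_error(exc)))
    return TableReadResult(records, rejections, n_input_rows=len(raw))


def _short_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        err = exc.errors()[0]
        return str(err.get("msg", exc))
    return str(exc)


def _build_effect(row: dict, side: str) -> Optional[EffectEstimate]:
    point = _parse_float(row[f"{side}_effect"])
    if point is None:
        return None
    return EffectEstimate(
        point=point,
        ci_low=_parse_float(row[f"{side}_ci_low"]),
        ci_high=_parse_float(row[f"{side}_ci_high"]),
        p_value=_parse_float(row[f"{side}_p_value"]),
        measure=Measure(row["measure"] or "HR"),
    )


def _build_pair(sid: str, rows: list[dict], rate_factor: float) -> StudyPair:
    first = rows[0]
    for key in ["design", "measure"] + ATTRIBUTE_COLUMNS:
        vals = {r[key] for r in rows}
        if len(vals) > 1:
            raise ValueError(f"study-level column {key!r} differs across arm rows")
    arms = {"original": [], "reproduction": []}
    for row in rows:
        for side in ("original", "reproduction"):
            rate = _parse_float(row[f"{side}_rate_per100py"])
            arms[side].append(
                ArmResult(
                    arm_id=row["arm_id"],
                    n=_parse_int(row[f"{side}_n"]) or 0,
                    events=_parse_int(row[f"{side}_events"]),
                    risk_pct=_parse_float(row[f"{side}_risk_pct"]),
                    rate_per100py=None if rate is None else rate * rate_factor,
                    person_years=_parse_float(row[f"{side}_person_years"]),
                    is_reference=_parse_bool(row["is_reference"]),
                )
            )
    attributes = {k: first[k] for k in ATTRIBUTE_COLUMNS if first[k] != ""}
    return StudyPair(
        study_id=sid,
        design=Design(first["design"]),
        original=StudyResult(arms=arms["original"], effect=_build_effect(first, "original")),
        reproduction=StudyResult(
            arms=arms["reproduction"], effect=_build_effect(first, "reproduction")
        ),
        attributes=attributes,
    )


def write_study_pairs(records: Sequence[StudyPair], path) -> Path:
    """Write studies.csv with deterministic column order and formatting."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(STUDY_COLUMNS)
        for rec in records:
            eff_o, eff_r = rec.original.effect, rec.reproduction.effect
            measure = eff_o.measure if eff_o is not None else Measure.HR
            for arm_o, arm_r in zip(rec.original.arms, rec.reproduction.arms):
                row = {
                    "study_id": rec.study_id,
                    "design": rec.design,
                    "measure": measure,
                    "arm_id": arm_o.arm_id,
                    "is_reference": arm_o.is_reference,
                }
                for side, arm in (("original", arm_o), ("reproduction", arm_r)):
                    row[f"{side}_n"] = arm.n
                    row[f"{side}_events"] = arm.events
                    row[f"{side}_risk_pct"] = arm.risk_pct
                    row[f"{side}_rate_per100py"] = arm.rate_per100py
                    row[f"{side}_person_years"] = arm.person_years
                for side, eff in (("original", eff_o), ("reproduction", eff_r)):
                    row[f"{side}_effect"] = None if eff is None else eff.point
                    row[f"{side}_ci_low"] = None if eff is None else eff.ci_low
                    row[f"{side}_ci_high"] = None if eff is None else eff.ci_high
                    row[f"{side}_p_value"] = None if eff is None else eff.p_value
                for k in ATTRIBUTE_COLUMNS:
                    row[k] = rec.attributes.get(k)
                w.writerow([_fmt(row[c]) for c in STUDY_COLUMNS])
    return path


def read_covariates(
    path,
    schema_version: str = SCHEMA_VERSION,
    column_map: Optional[dict] = None,
) -> TableReadResult:
    _check_schema_version(schema_version)
    raw = _open_table(path, COVARIATE_COLUMNS, column_map)
    records, rejections = [], []
    for i, row in enumerate(raw, start=1):
        try:
            records.append(
                CovariateEntry(
                    study_id=row["study_id"],
                    covariate=row["covariate"],
                    arm_id=row["arm_id"],
                    prev_original_pct=float(row["prev_original_pct"]),
                    prev_reproduction_pct=float(row["prev_reproduction_pct"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            rejections.append(Rejection(i, row["study_id"], _short_error(exc)))
    return TableReadResult(records, rejections, n_input_rows=len(raw))


def write_covariates(records: Sequence[CovariateEntry], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(COVARIATE_COLUMNS)
        for rec in records:
            w.writerow(
                [
                    rec.study_id,
                    rec.covariate,
                    rec.arm_id,
                    _fmt(rec.prev_original_pct),
                    _fmt(rec.prev_reproduction_pct),
                ]
            )
    return path


def read_checklist(
    path,
    schema_version: str = SCHEMA_VERSION,
    column_map: Optional[dict] = None,
) -> TableReadResult:
    """Read checklist.csv into :class:`rwerepro.reporting_clarity.ChecklistRecord`."""
    from .reporting_clarity import CHECKLIST_COLUMNS, checklist_record_from_row

    _check_schema_version(schema_version)
    raw = _open_table(path, CHECKLIST_COLUMNS, column_map)
    records, rejections = [], []
    for i, row in enumerate(raw, start=1):
        try:
            records.append(checklist_record_from_row(row))
        except (ValidationError, ValueError) as exc:
            rejections.append(Rejection(i, row["study_id"], _short_error(exc)))
    return TableReadResult(records, rejections, n_input_rows=len(raw))


def write_checklist(records, path) -> Path:
    from .reporting_clarity import CHECKLIST_COLUMNS, checklist_record_to_row

    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CHECKLIST_COLUMNS)
        for rec in records:
            row = checklist_record_to_row(rec)
            w.writerow([_fmt(row[c]) for c in CHECKLIST_COLUMNS])
    return path
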