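"""Patient/cohort data model and delimited-file I/O.

A cohort is an ordered collection of admissions of ST-elevation myocardial
infarction (STEMI) patients treated with percutaneous coronary intervention.
Each record carries the demographics and admission vitals that feed the
Shock Index-C score (age, sex, heart rate, systolic blood pressure, serum
creatinine, optionally weight), the in-hospital outcome flags, and optional
1-year follow-up.

Files are plain delimited text (comma by default, tab accepted) with a
header row. Column names can be remapped through a ``schema`` dictionary
``{canonical_name: column_name_in_file}``. Unrecognised columns are kept as
string ``extras`` so precomputed comparator scores (GRACE, TIMI, ...) can
ride along.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "Sex",
    "CohortLabel",
    "PatientRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "derive_mace",
    "REQUIRED_COLUMNS",
    "FLAG_COLUMNS",
]


class Sex(str, Enum):
    """Biological sex; a closed two-value set because the Cockcroft-Gault
    creatinine-clearance estimate is sex-specific."""

    MALE = "male"
    FEMALE = "female"


class CohortLabel(str, Enum):
    DERIVATION = "derivation"
    VALIDATION = "validation"
    UNSPECIFIED = "unspecified"


#: canonical column order for reading and writing
REQUIRED_COLUMNS = ("age", "sex", "heart_rate", "sbp", "scr")
FLAG_COLUMNS = (
    "death",
    "stroke",
    "acute_heart_failure",
    "dialysis",
    "tvr",
    "ci_aki",
    "bleeding",
)
_OPTIONAL_NUMERIC = ("weight", "followup_days")
_ALL_COLUMNS = (
    ("patient_id",)
    + REQUIRED_COLUMNS[:2]
    + ("weight",)
    + REQUIRED_COLUMNS[2:]
    + FLAG_COLUMNS
    + ("followup_days", "death_1y", "cohort_label")
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class PatientRecord:
    """One admission. Optional fields are ``None`` when absent; nothing is
    ever imputed — operations that need a missing field fail loudly."""

    patient_id: str
    age: float
    sex: Sex
    heart_rate: float
    sbp: float
    scr: float
    weight: float | None = None
    death: bool | None = None
    stroke: bool | None = None
    acute_heart_failure: bool | None = None
    dialysis: bool | None = None
    tvr: bool | None = None
    ci_aki: bool | None = None
    bleeding: bool | None = None
    followup_days: float | None = None
    death_1y: bool | None = None
    cohort_label: CohortLabel = CohortLabel.UNSPECIFIED
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "cohort_label", CohortLabel(self.cohort_label))
        _check(self.heart_rate > 0, f"heart_rate must be > 0, got {self.heart_rate}")
        _check(self.sbp > 0, f"sbp must be > 0, got {self.sbp}")
        _check(self.scr > 0, f"scr must be > 0, got {self.scr}")
        _check(18 <= self.age < 120, f"age must be in [18, 120), got {self.age}")
        if self.weight is not None:
            _check(self.weight > 0, f"weight must be > 0, got {self.weight}")
        if self.followup_days is not None:
            _check(self.followup_days >= 0,
                   f"followup_days must be >= 0, got {self.followup_days}")
        if self.death_1y is not None:
            _check(self.followup_days is not None,
                   "death_1y requires followup_days to be present")

    def with_(self, **changes) -> "PatientRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class Cohort:
    """Ordered, non-empty collection of records with unique patient ids."""

    records: tuple[PatientRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        _check(len(self.records) > 0, "cohort must be non-empty")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate patient_id {dup!r} in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Typed DataFrame view (one row per record, canonical columns first,
        extras appended as strings)."""
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex.value,
                "weight": r.weight,
                "heart_rate": r.heart_rate,
                "sbp": r.sbp,
                "scr": r.scr,
                "followup_days": r.followup_days,
                "cohort_label": r.cohort_label.value,
            }
            for f in FLAG_COLUMNS + ("death_1y",):
                row[f] = getattr(r, f)
            row.update(r.extras)
            rows.append(row)
        return pd.DataFrame(rows)


def derive_mace(record: PatientRecord) -> bool:
    """In-hospital major adverse clinical events composite.

    True iff at least one of stroke, dialysis, acute heart failure, or
    target-vessel revascularisation occurred. Death is accounted separately
    and is deliberately not part of the composite.
    """
    components = (record.stroke, record.dialysis,
                  record.acute_heart_failure, record.tvr)
    if any(c is None for c in components):
        missing = [n for n, c in zip(
            ("stroke", "dialysis", "acute_heart_failure", "tvr"), components)
            if c is None]
        raise ValidationError(f"MACE components missing: {', '.join(missing)}")
    return any(components)


def _parse_float(cell: str, row: int, col: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"row {row}: cannot parse {col}={cell!r} as a number") from None


def _parse_flag(cell: str, row: int, col: str) -> bool:
    low = cell.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ParseError(
        f"row {row}: cannot parse {col}={cell!r} as a flag "
        "(accepted: 0/1/true/false/yes/no)")


def read_cohort(path: str | Path,
                schema: Mapping[str, str] | None = None,
                delimiter: str | None = None,
                label: str = "") -> Cohort:
    """Read a delimited cohort file into a :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited text file with a header row (UTF-8).
    schema
        Optional mapping ``{canonical_name: column_name_in_file}`` overriding
        the default identity mapping for any subset of canonical columns.
    delimiter
        Field delimiter; when ``None`` it is sniffed from the header
        (comma default, tab accepted).

    Raises
    ------
    SchemaError
        If a required column (age, sex, heart_rate, sbp, scr) is absent.
    ValidationError / ParseError
        Naming the offending row (0-based data row index) and field.
    """
    path = Path(path)
    schema = dict(schema or {})
    with path.open(newline="", encoding="utf-8") as fh:
        head = fh.readline()
        if delimiter is None:
            delimiter = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        colmap = {canon: schema.get(canon, canon) for canon in _ALL_COLUMNS}
        for canon in REQUIRED_COLUMNS:
            if colmap[canon] not in header:
                raise SchemaError(
                    f"required column {canon!r} (file column {colmap[canon]!r}) "
                    f"not found in header {header}")
        mapped = {v for k, v in colmap.items() if v in header}
        extra_cols = [c for c in header if c not in mapped]

        records: list[PatientRecord] = []
        for i, raw in enumerate(reader):
            def cell(canon: str) -> str:
                c = colmap[canon]
                return (raw.get(c) or "").strip()

            kw: dict = {}
            pid = cell("patient_id")
            kw["patient_id"] = pid if pid else f"p{i:06d}"
            sex = cell("sex").lower()
            if sex not in ("male", "female"):
                raise ValidationError(
                    f"row {i}: sex must be 'male' or 'female', got {cell('sex')!r}")
            kw["sex"] = Sex(sex)
            for col in ("age", "heart_rate", "sbp", "scr"):
                kw[col] = _parse_float(cell(col), i, col)
            for col in _OPTIONAL_NUMERIC:
                v = cell(col)
                kw[col] = _parse_float(v, i, col) if v else None
            for col in FLAG_COLUMNS + ("death_1y",):
                v = cell(col)
                kw[col] = _parse_flag(v, i, col) if v else None
            lab = cell("cohort_label")
            if lab:
                try:
                    kw["cohort_label"] = CohortLabel(lab.lower())
                except ValueError:
                    raise ValidationError(
                        f"row {i}: unknown cohort_label {lab!r}") from None
            kw["extras"] = {c: (raw.get(c) or "") for c in extra_cols}
            try:
                records.append(PatientRecord(**kw))
            except ValidationError as e:
                raise ValidationError(f"row {i}: {e}") from None
    return Cohort(tuple(records), label=label or path.stem)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return "" if math.isnan(v) else repr(v)
    return str(v)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> Path:
    """Write a cohort to a delimited text file re-readable by
    :func:`read_cohort`. Floats keep full precision; absent optional fields
    become empty cells."""
    path = Path(path)
    extra_cols: list[str] = []
    for r in cohort:
        for c in r.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(list(_ALL_COLUMNS) + extra_cols)
        for r in cohort:
            row = [
                r.patient_id, _fmt(float(r.age)), r.sex.value, _fmt(r.weight),
                _fmt(float(r.heart_rate)), _fmt(float(r.sbp)), _fmt(float(r.scr)),
            ]
            row += [_fmt(getattr(r, f)) for f in FLAG_COLUMNS]
            row += [_fmt(r.followup_days), _fmt(r.death_1y), r.cohort_label.value]
            row += [r.extras.get(c, "") for c in extra_cols]
            w.writerow(row)
    return path
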