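"""Domain model for verbal-autopsy (VA) records.

A VA record captures one out-of-facility death: demographics, binary symptom
endorsements collected from the family interview, and the pathway flags a
certifying physician needs (are medical records available, could the open
narrative alone support a diagnosis). Records are routed to one of three
questionnaire modules by age: neonate (first 28 days), child (28 days up to
12 years), adult (12 years and above).

This module owns the symptom schema, the cause list, CSV ingestion with
row-level error collection, and record validation. Field data is dirty;
parsing therefore skips unusable rows and reports them rather than aborting
a batch.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .errors import SchemaError, ValidationError

logger = logging.getLogger("autova")

DAYS_PER_YEAR = 365.25

MODULE_NEONATE = "neonate"
MODULE_CHILD = "child"
MODULE_ADULT = "adult"
MODULES = (MODULE_NEONATE, MODULE_CHILD, MODULE_ADULT)

SEXES = ("male", "female")

#: Label the engine emits when no cause passes the thresholds; physicians may
#: also certify ICD-10 garbage codes which the default ill-defined set covers.
UNDETERMINED = "undetermined"
DEFAULT_ILL_DEFINED_CODES = frozenset({"R99", "I46", "R54"})

REQUIRED_COLUMNS = (
    "death_id",
    "age_value",
    "age_unit",
    "sex",
    "medical_records_available",
)
OPTIONAL_FLAG_COLUMNS = (
    "narrative_confident",
    "records_confident",
    "respondent_is_family",
)

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


def parse_bool(token: str, *, default: Optional[bool] = None) -> bool:
    """Parse a CSV boolean cell; accepts 0/1/true/false/yes/no, any case."""
    token = token.strip().lower()
    if not token:
        if default is None:
            raise ValidationError("empty boolean cell")
        return default
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValidationError(f"cannot parse boolean value {token!r}")


@dataclass(frozen=True)
class SymptomSchema:
    """Ordered binary symptom list for one questionnaire module."""

    module_id: str
    symptoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.module_id not in MODULES:
            raise ValidationError(f"unknown module_id {self.module_id!r}")
        if not self.symptoms:
            raise ValidationError("symptom list must be non-empty")
        if len(set(self.symptoms)) != len(self.symptoms):
            raise ValidationError("symptom ids must be unique within a module")
        object.__setattr__(self, "symptoms", tuple(self.symptoms))


@dataclass(frozen=True)
class CauseList:
    """Cause universe with its ill-defined subset and category aggregation."""

    causes: tuple[str, ...]
    ill_defined_codes: frozenset[str] = DEFAULT_ILL_DEFINED_CODES
    category_map: Mapping[str, str] = field(default_factory=dict)
    residual_category: str = "other"

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ValidationError("cause ids must be unique")
        object.__setattr__(self, "causes", tuple(self.causes))
        object.__setattr__(self, "ill_defined_codes", frozenset(self.ill_defined_codes))


@dataclass
class VARecord:
    """One death: demographics, endorsements, and certification-pathway flags.

    ``endorsements`` maps symptom id to 1 (endorsed), 0 (not endorsed) or
    ``None`` (missing). ``true_cause`` is populated only for synthetic cohorts
    where ground truth is known.
    """

    death_id: str
    age_value: float
    age_unit: str
    sex: str
    endorsements: dict[str, Optional[int]]
    medical_records_available: bool
    narrative_confident: bool = False
    records_confident: bool = False
    respondent_is_family: bool = True
    module_id: str = ""
    true_cause: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.module_id:
            self.module_id = assign_age_module(self.age_value, self.age_unit)

    @property
    def endorsed_symptoms(self) -> list[str]:
        return [s for s, v in self.endorsements.items() if v == 1]


@dataclass(frozen=True)
class Issue:
    """One validation finding; data, not an exception."""

    death_id: str
    field: str
    description: str


@dataclass(frozen=True)
class RowError:
    """A row skipped during parsing, with a machine-readable reason."""

    row_number: int
    death_id: str
    description: str


@dataclass
class ParseResult:
    """Parsed records plus the row-level error report."""

    records: list[VARecord]
    errors: list[RowError]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def age_in_days(age_value: float, age_unit: str) -> float:
    """Convert an age to days (years at 365.25 days/year)."""
    try:
        value = float(age_value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"unparseable age {age_value!r}") from exc
    if value < 0:
        raise ValidationError(f"age must be non-negative, got {value}")
    if age_unit == "days":
        return value
    if age_unit == "years":
        return value * DAYS_PER_YEAR
    raise ValidationError(f"unknown age unit {age_unit!r} (expected days or years)")


def assign_age_module(age_value: float, age_unit: str) -> str:
    """Route an age to its questionnaire module.

    Bands are half-open so they are exhaustive and disjoint: [0, 28) days is
    the neonate module, [28 days, 12 years) the child module, and 12 years or
    older the adult module.
    """
    days = age_in_days(age_value, age_unit)
    if days < 28:
        return MODULE_NEONATE
    if days < 12 * DAYS_PER_YEAR:
        return MODULE_CHILD
    return MODULE_ADULT


def _parse_endorsement(cell: str) -> Optional[int]:
    cell = cell.strip().lower()
    if not cell:
        return None
    if cell in _TRUE_TOKENS:
        return 1
    if cell in _FALSE_TOKENS:
        return 0
    raise ValidationError(f"cannot parse endorsement value {cell!r}")


def parse_va_records(
    csv_source: Union[str, Path, io.TextIOBase],
    schema: SymptomSchema,
) -> ParseResult:
    """Read field VA records from a flat CSV export.

    Required columns: death_id, age_value, age_unit, sex,
    medical_records_available. Symptom columns are named by symptom id; blank
    symptom cells become missing. Rows that cannot be parsed are skipped and
    reported in :class:`ParseResult.errors`; duplicate death ids and missing
    required columns abort the whole batch.
    """
    if isinstance(csv_source, (str, Path)):
        with open(csv_source, newline="", encoding="utf-8") as handle:
            return parse_va_records(handle, schema)

    reader = csv.DictReader(csv_source)
    header = reader.fieldnames or []
    for column in REQUIRED_COLUMNS:
        if column not in header:
            raise SchemaError(f"missing required column {column!r}")
    symptom_columns = [s for s in schema.symptoms if s in header]

    records: list[VARecord] = []
    errors: list[RowError] = []
    seen_ids: set[str] = set()
    for row_number, row in enumerate(reader, start=2):
        death_id = (row.get("death_id") or "").strip()
        try:
            if not death_id:
                raise ValidationError("empty death_id")
            if death_id in seen_ids:
                raise SchemaError(f"duplicate death_id {death_id!r}")
            sex = (row.get("sex") or "").strip().lower()
            if sex not in SEXES:
                raise ValidationError(f"unknown sex {sex!r}")
            age_unit = (row.get("age_unit") or "").strip().lower()
            age_value = float((row.get("age_value") or "").strip())
            endorsements: dict[str, Optional[int]] = {
                s: _parse_endorsement(row.get(s) or "") for s in symptom_columns
            }
            record = VARecord(
                death_id=death_id,
                age_value=age_value,
                age_unit=age_unit,
                sex=sex,
                endorsements=endorsements,
                medical_records_available=parse_bool(
                    row.get("medical_records_available") or ""
                ),
                narrative_confident=parse_bool(
                    row.get("narrative_confident") or "", default=False
                ),
                records_confident=parse_bool(
                    row.get("records_confident") or "", default=False
                ),
                respondent_is_family=parse_bool(
                    row.get("respondent_is_family") or "", default=True
                ),
                true_cause=(row.get("true_cause") or "").strip() or None,
            )
        except SchemaError:
            raise
        except (ValidationError, ValueError) as exc:
            logger.warning("skipping row %d (%s): %s", row_number, death_id, exc)
            errors.append(RowError(row_number, death_id, str(exc)))
            continue
        seen_ids.add(death_id)
        records.append(record)
    return ParseResult(records=records, errors=errors)


def write_va_records(
    records: Iterable[VARecord],
    destination: Union[str, Path, io.TextIOBase],
    schema: SymptomSchema,
) -> None:
    """Write records back to the flat CSV layout read by parse_va_records."""
    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="", encoding="utf-8") as handle:
            write_va_records(records, handle, schema)
            return

    columns = (
        list(REQUIRED_COLUMNS)
        + list(OPTIONAL_FLAG_COLUMNS)
        + ["true_cause"]
        + list(schema.symptoms)
    )
    writer = csv.DictWriter(destination, fieldnames=columns)
    writer.writeheader()
    for record in records:
        row: dict[str, str] = {
            "death_id": record.death_id,
            "age_value": format(record.age_value, "g"),
            "age_unit": record.age_unit,
            "sex": record.sex,
            "medical_records_available": str(int(record.medical_records_available)),
            "narrative_confident": str(int(record.narrative_confident)),
            "records_confident": str(int(record.records_confident)),
            "respondent_is_family": str(int(record.respondent_is_family)),
            "true_cause": record.true_cause or "",
        }
        for symptom in schema.symptoms:
            value = record.endorsements.get(symptom)
            row[symptom] = "" if value is None else str(value)
        writer.writerow(row)


def validate_record(record: VARecord, schema: SymptomSchema) -> list[Issue]:
    """Check a record against the domain invariants; issues are data."""
    issues: list[Issue] = []
    try:
        expected_module = assign_age_module(record.age_value, record.age_unit)
    except ValidationError as exc:
        issues.append(Issue(record.death_id, "age_value", str(exc)))
        expected_module = None
    if expected_module is not None and record.module_id != expected_module:
        issues.append(
            Issue(
                record.death_id,
                "module_id",
                f"module_id {record.module_id!r} inconsistent with age "
                f"(expected {expected_module!r})",
            )
        )
    if record.sex not in SEXES:
        issues.append(Issue(record.death_id, "sex", f"unknown sex {record.sex!r}"))
    unknown = set(record.endorsements) - set(schema.symptoms)
    for symptom in sorted(unknown):
        issues.append(
            Issue(
                record.death_id,
                "endorsements",
                f"endorsement key {symptom!r} not in schema",
            )
        )
    for symptom, value in record.endorsements.items():
        if value not in (0, 1, None):
            issues.append(
                Issue(
                    record.death_id,
                    "endorsements",
                    f"endorsement for {symptom!r} must be 0, 1 or missing",
                )
            )
    return issues
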