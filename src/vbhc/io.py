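"""Delimited-text readers and writers for the three hospital datasets.

The canonical on-disk layout is five CSV files:

``clinical.csv``
    one row per patient (case-mix variables, vital status, flags), with
    long-format companions ``treatments.csv``, ``proms.csv`` and
    ``complications.csv`` in the same directory;
``service.csv``
    one row per service claim;
``costs.csv``
    one row per cost line (no patient identifier, by construction).

Dates are ISO-8601 (``YYYY-MM-DD``).  Money is parsed into exact
:class:`~decimal.Decimal` with two fractional digits.  Delimiter and
decimal mark are configurable because Swiss accounting exports commonly
use ``;`` with ``,`` as the decimal mark.

Malformed rows are rejected individually with line-level diagnostics;
violations of dataset-wide key invariants (duplicate patient IDs, a case
number claimed by two patients) abort the read, because silently keeping
either record would corrupt every downstream linkage step.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Optional

from .records import (
    CaseType,
    Comorbidity,
    Complication,
    CostRecord,
    Histology,
    Modality,
    PatientClinicalRecord,
    PromAssessment,
    ServiceClaim,
    Sex,
    Smoking,
    Stage,
    Timepoint,
    TreatmentEpisode,
    VitalStatus,
    chf,
)

log = logging.getLogger(__name__)


class DataFormatError(ValueError):
    """Hard error: the file violates a dataset-wide invariant."""


@dataclass(frozen=True)
class Dialect:
    delimiter: str = ","
    decimal_mark: str = "."


@dataclass(frozen=True)
class RowError:
    path: str
    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}:{self.line}: {self.message}"


@dataclass
class ParseLog:
    """Accumulates row-level rejections from one read call."""

    errors: list[RowError] = field(default_factory=list)

    def reject(self, path: Path, line: int, message: str) -> None:
        err = RowError(str(path), line, message)
        self.errors.append(err)
        log.warning("rejected row %s", err)


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value.strip())


def _parse_money(value: str, dialect: Dialect) -> Decimal:
    text = value.strip()
    if dialect.decimal_mark != ".":
        text = text.replace(dialect.decimal_mark, ".")
    amount = Decimal(text)
    if not amount.is_finite():
        raise InvalidOperation(f"non-finite amount {value!r}")
    return chf(amount)


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _fmt_number(value: float) -> str:
    return f"{value:g}"


def _rows(path: Path, dialect: Dialect, required: Iterable[str]):
    """Yield (line_number, row_dict); validate the header up front."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise DataFormatError(f"{path}: missing required columns {missing}")
        for i, row in enumerate(reader, start=2):
            yield i, row


# ---------------------------------------------------------------------------
# clinical dataset

CLINICAL_COLUMNS = [
    "patient_id",
    "diagnosis_date",
    "histology",
    "stage",
    "sex",
    "age_at_diagnosis",
    "comorbidity_category",
    "smoking_status",
    "trial_participant",
    "residency_region",
    "vital_status",
    "status_date",
    "death_in_hospital",
    "deactivation_reason",
]
TREATMENT_COLUMNS = ["patient_id", "modality", "start_date", "end_date"]
PROM_COLUMNS = ["patient_id", "timepoint", "assessment_date", "qlq_c30_summary_score"]
COMPLICATION_COLUMNS = ["patient_id", "label", "start_date", "end_date"]
SERVICE_COLUMNS = [
    "patient_id",
    "case_number",
    "service_date",
    "case_type",
    "admitting_unit",
    "executing_unit",
    "service_text",
    "service_type",
    "quantity",
]
COST_COLUMNS = [
    "case_number",
    "cost_amount",
    "billing_month",
    "billing_year",
    "cost_centre_type",
]


def read_clinical(
    path: str | Path,
    dialect: Dialect = Dialect(),
    *,
    treatments_path: str | Path | None = None,
    proms_path: str | Path | None = None,
    complications_path: str | Path | None = None,
    parse_log: ParseLog | None = None,
) -> list[PatientClinicalRecord]:
    """Read the clinical dataset (wide patient file plus long companions).

    Companion paths default to ``treatments.csv``, ``proms.csv`` and
    ``complications.csv`` next to ``path``; a missing companion file is
    treated as empty.  Invalid rows are rejected with line diagnostics;
    a duplicate ``patient_id`` is a hard error.
    """
    path = Path(path)
    parse_log = parse_log if parse_log is not None else ParseLog()
    records: dict[str, PatientClinicalRecord] = {}

    for line, row in _rows(path, dialect, CLINICAL_COLUMNS):
        try:
            pid = row["patient_id"].strip()
            if not pid:
                raise ValueError("empty patient_id")
            if pid in records:
                raise DataFormatError(
                    f"{path}:{line}: duplicate patient_id {pid!r}"
                )
            rec = PatientClinicalRecord(
                patient_id=pid,
                diagnosis_date=_parse_date(row["diagnosis_date"]),
                histology=Histology(row["histology"].strip()),
                stage=Stage(row["stage"].strip()),
                sex=Sex(row["sex"].strip()),
                age_at_diagnosis=int(row["age_at_diagnosis"]),
                comorbidity_category=Comorbidity(row["comorbidity_category"].strip()),
                smoking_status=Smoking(row["smoking_status"].strip()),
                trial_participant=_parse_bool(row["trial_participant"]),
                residency_region=row["residency_region"].strip(),
                vital_status=VitalStatus(row["vital_status"].strip()),
                status_date=_parse_date(row["status_date"]),
                death_in_hospital=_parse_bool(row["death_in_hospital"]),
                deactivation_reason=row["deactivation_reason"].strip() or None,
            )
            if rec.status_date < rec.diagnosis_date:
                raise ValueError(
                    f"status_date {rec.status_date} before diagnosis "
                    f"{rec.diagnosis_date}"
                )
        except DataFormatError:
            raise
        except (ValueError, KeyError, InvalidOperation) as exc:
            parse_log.reject(path, line, str(exc))
            continue
        records[pid] = rec

    _read_treatments(
        Path(treatments_path) if treatments_path else path.parent / "treatments.csv",
        dialect, records, parse_log,
    )
    _read_proms(
        Path(proms_path) if proms_path else path.parent / "proms.csv",
        dialect, records, parse_log,
    )
    _read_complications(
        Path(complications_path)
        if complications_path
        else path.parent / "complications.csv",
        dialect, records, parse_log,
    )
    return list(records.values())


def _read_treatments(path, dialect, records, parse_log):
    if not path.exists():
        return
    for line, row in _rows(path, dialect, TREATMENT_COLUMNS):
        try:
            pid = row["patient_id"].strip()
            rec = records.get(pid)
            if rec is None:
                raise ValueError(f"unknown patient_id {pid!r}")
            ep = TreatmentEpisode(
                modality=Modality(row["modality"].strip()),
                start_date=_parse_date(row["start_date"]),
                end_date=_parse_date(row["end_date"]),
            )
            if ep.start_date < rec.diagnosis_date:
                log.warning(
                    "patient %s: treatment %s starts %s before diagnosis %s",
                    pid, ep.modality.value, ep.start_date, rec.diagnosis_date,
                )
            rec.treatments.append(ep)
        except ValueError as exc:
            parse_log.reject(path, line, str(exc))


def _read_proms(path, dialect, records, parse_log):
    if not path.exists():
        return
    for line, row in _rows(path, dialect, PROM_COLUMNS):
        try:
            pid = row["patient_id"].strip()
            rec = records.get(pid)
            if rec is None:
                raise ValueError(f"unknown patient_id {pid!r}")
            tp = Timepoint(row["timepoint"].strip())
            if rec.prom(tp) is not None:
                raise ValueError(f"duplicate PROM timepoint {tp.value} for {pid!r}")
            raw = row["qlq_c30_summary_score"].strip()
            rec.prom_assessments.append(
                PromAssessment(
                    timepoint=tp,
                    assessment_date=_parse_date(row["assessment_date"]),
                    qlq_c30_summary_score=float(raw) if raw else None,
                )
            )
        except ValueError as exc:
            parse_log.reject(path, line, str(exc))


def _read_complications(path, dialect, records, parse_log):
    if not path.exists():
        return
    for line, row in _rows(path, dialect, COMPLICATION_COLUMNS):
        try:
            pid = row["patient_id"].strip()
            rec = records.get(pid)
            if rec is None:
                raise ValueError(f"unknown patient_id {pid!r}")
            rec.complications.append(
                Complication(
                    label=row["label"].strip(),
                    start_date=_parse_date(row["start_date"]),
                    end_date=_parse_date(row["end_date"]),
                )
            )
        except ValueError as exc:
            parse_log.reject(path, line, str(exc))


# ---------------------------------------------------------------------------
# service dataset


def read_service(
    path: str | Path,
    dialect: Dialect = Dialect(),
    *,
    parse_log: ParseLog | None = None,
) -> list[ServiceClaim]:
    """Read service claims; enforce one patient and one case type per case."""
    path = Path(path)
    parse_log = parse_log if parse_log is not None else ParseLog()
    claims: list[ServiceClaim] = []
    case_owner: dict[str, tuple[str, CaseType]] = {}

    for line, row in _rows(path, dialect, SERVICE_COLUMNS):
        try:
            qty_raw = row.get("quantity", "").strip()
            claim = ServiceClaim(
                patient_id=row["patient_id"].strip(),
                case_number=row["case_number"].strip(),
                service_date=_parse_date(row["service_date"]),
                case_type=CaseType(row["case_type"].strip()),
                admitting_unit=row["admitting_unit"].strip(),
                executing_unit=row["executing_unit"].strip(),
                service_text=row["service_text"],
                service_type=row.get("service_type", "").strip(),
                quantity=float(qty_raw) if qty_raw else 1.0,
            )
        except ValueError as exc:
            parse_log.reject(path, line, str(exc))
            continue
        key = (claim.patient_id, claim.case_type)
        seen = case_owner.setdefault(claim.case_number, key)
        if seen != key:
            raise DataFormatError(
                f"{path}:{line}: case number {claim.case_number!r} is claimed by "
                f"patient {seen[0]!r} as {seen[1].value} and by "
                f"patient {key[0]!r} as {key[1].value}"
            )
        claims.append(claim)
    return claims


def read_costs(
    path: str | Path,
    dialect: Dialect = Dialect(),
    *,
    parse_log: ParseLog | None = None,
) -> list[CostRecord]:
    path = Path(path)
    parse_log = parse_log if parse_log is not None else ParseLog()
    costs: list[CostRecord] = []
    for line, row in _rows(path, dialect, COST_COLUMNS):
        try:
            costs.append(
                CostRecord(
                    case_number=row["case_number"].strip(),
                    cost_amount=_parse_money(row["cost_amount"], dialect),
                    billing_month=int(row["billing_month"]),
                    billing_year=int(row["billing_year"]),
                    cost_centre_type=row["cost_centre_type"].strip(),
                )
            )
        except (ValueError, InvalidOperation) as exc:
            parse_log.reject(path, line, str(exc))
    return costs


# ---------------------------------------------------------------------------
# writers (canonical dialect; deterministic row order as given)


def _writer(fh, dialect: Dialect):
    return csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")


def _fmt_money(amount: Decimal, dialect: Dialect) -> str:
    text = f"{chf(amount)}"
    if dialect.decimal_mark != ".":
        text = text.replace(".", dialect.decimal_mark)
    return text


def write_clinical(
    records: Iterable[PatientClinicalRecord],
    directory: str | Path,
    dialect: Dialect = Dialect(),
) -> None:
    """Write clinical.csv plus its three long-format companion files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = list(records)
    with open(directory / "clinical.csv", "w", newline="") as fh:
        w = _writer(fh, dialect)
        w.writerow(CLINICAL_COLUMNS)
        for r in records:
            w.writerow([
                r.patient_id,
                r.diagnosis_date.isoformat(),
                r.histology.value,
                r.stage.value,
                r.sex.value,
                r.age_at_diagnosis,
                r.comorbidity_category.value,
                r.smoking_status.value,
                str(r.trial_participant).lower(),
                r.residency_region,
                r.vital_status.value,
                r.status_date.isoformat(),
                str(r.death_in_hospital).lower(),
                r.deactivation_reason or "",
            ])
    with open(directory / "treatments.csv", "w", newline="") as fh:
        w = _writer(fh, dialect)
        w.writerow(TREATMENT_COLUMNS)
        for r in records:
            for ep in r.treatments:
                w.writerow([
                    r.patient_id,
                    ep.modality.value,
                    ep.start_date.isoformat(),
                    ep.end_date.isoformat(),
                ])
    with open(directory / "proms.csv", "w", newline="") as fh:
        w = _writer(fh, dialect)
        w.writerow(PROM_COLUMNS)
        for r in records:
            for a in r.prom_assessments:
                score = a.qlq_c30_summary_score
                w.writerow([
                    r.patient_id,
                    a.timepoint.value,
                    a.assessment_date.isoformat(),
                    "" if score is None else _fmt_number(score),
                ])
    with open(directory / "complications.csv", "w", newline="") as fh:
        w = _writer(fh, dialect)
        w.writerow(COMPLICATION_COLUMNS)
        for r in records:
            for c in r.complications:
                w.writerow([
                    r.patient_id,
                    c.label,
                    c.start_date.isoformat(),
                    c.end_date.isoformat(),
                ])


def write_service(
    claims: Iterable[ServiceClaim],
    path: str | Path,
    dialect: Dialect = Dialect(),
) -> None:
    with open(path, "w", newline="") as fh:
        w = _writer(fh, dialect)
        w.writerow(SERVICE_COLUMNS)
        for c in claims:
            w.writerow([
                c.patient_id,
                c.case_number,
                c.service_date.isoformat(),
                c.case_type.value,
                c.admitting_unit,
                c.executing_unit,
                c.service_text,
                c.service_type,
                _fmt_number(c.quantity),
            ])


def write_costs(
    costs: Iterable[CostRecord],
    path: str | Path,
    dialect: Dialect = Dialect(),
) -> None:
    with open(path, "w", newline="") as fh:
        w = _writer(fh, dialect)
        w.writerow(COST_COLUMNS)
        for c in costs:
            w.writerow([
                c.case_number,
                _fmt_money(c.cost_amount, dialect),
                c.billing_month,
                c.billing_year,
                c.cost_centre_type,
            ])
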