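"""Domain types for the three routinely collected hospital datasets.

Swiss hospitals keep three disconnected tables: a clinical dataset (one
record per patient, with clinician- and patient-reported outcomes), a
service dataset (one row per billed service claim, keyed by patient ID
*and* case number) and a cost dataset produced by the REKOLE cost
accounting system (one row per cost line, keyed by case number only —
it deliberately carries no patient identifier).  The case number is the
billing unit: one per inpatient stay, or one per up-to-12-month
outpatient episode for the same main diagnosis, and it is the only key
shared between the service and the cost datasets.

Money is represented as :class:`decimal.Decimal` quantised to 0.01 CHF
throughout; nothing in the merge pipeline accumulates floating point.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import Decimal
from enum import Enum
from typing import Optional

CENT = Decimal("0.01")


def chf(value) -> Decimal:
    """Coerce ``value`` to a Decimal CHF amount with exactly 2 decimals."""
    return Decimal(str(value)).quantize(CENT)


class Histology(str, Enum):
    ADENOCARCINOMA = "adenocarcinoma"
    SQUAMOUS_CELL = "squamous_cell"
    SMALL_CELL = "small_cell"
    NSCLC_OTHER = "NSCLC_other"
    OTHER = "other"


class Stage(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Comorbidity(str, Enum):
    NONE = "none"
    LOW = "low"
    MODERATE = "moderate"
    SEVERE = "severe"
    MISSING = "missing"


class Smoking(str, Enum):
    NEVER = "never"
    EX = "ex"
    CURRENT = "current"
    MISSING = "missing"


class VitalStatus(str, Enum):
    ALIVE = "alive"
    DEAD = "dead"
    DEACTIVATED = "deactivated"


class Modality(str, Enum):
    """The five overarching treatment categories recorded clinically."""

    SURGERY = "surgery"
    CHEMOTHERAPY = "chemotherapy"
    RADIOTHERAPY = "radiotherapy"
    IMMUNOTHERAPY = "immunotherapy"
    TARGETED_THERAPY = "targeted_therapy"


SYSTEMIC_MODALITIES = frozenset(
    {Modality.CHEMOTHERAPY, Modality.IMMUNOTHERAPY, Modality.TARGETED_THERAPY}
)

#: Non-treatment assignment categories used in merge step 2.
CATEGORY_DIAGNOSIS = "diagnosis"
CATEGORY_OTHER = "other"
CATEGORY_DEATH = "death_in_hospital"


class Timepoint(str, Enum):
    BL = "BL"
    M3 = "M3"
    M6 = "M6"
    M12 = "M12"


class CaseType(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


@dataclass(frozen=True, slots=True)
class TreatmentEpisode:
    modality: Modality
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise ValueError(
                f"treatment episode start {self.start_date} after end {self.end_date}"
            )


@dataclass(frozen=True, slots=True)
class Complication:
    label: str
    start_date: dt.date
    end_date: dt.date


@dataclass(frozen=True, slots=True)
class PromAssessment:
    timepoint: Timepoint
    assessment_date: dt.date
    qlq_c30_summary_score: Optional[float]  # 0-100, None when missing

    def __post_init__(self):
        s = self.qlq_c30_summary_score
        if s is not None and not (0.0 <= s <= 100.0):
            raise ValueError(f"QLQ-C30 summary score {s} outside [0, 100]")


@dataclass(slots=True)
class PatientClinicalRecord:
    patient_id: str
    diagnosis_date: dt.date
    histology: Histology
    stage: Stage
    sex: Sex
    age_at_diagnosis: int
    comorbidity_category: Comorbidity
    smoking_status: Smoking
    trial_participant: bool
    residency_region: str
    vital_status: VitalStatus
    status_date: dt.date
    death_in_hospital: bool = False
    deactivation_reason: Optional[str] = None
    treatments: list[TreatmentEpisode] = field(default_factory=list)
    complications: list[Complication] = field(default_factory=list)
    prom_assessments: list[PromAssessment] = field(default_factory=list)

    def first_treatment_start(self) -> Optional[dt.date]:
        if not self.treatments:
            return None
        return min(ep.start_date for ep in self.treatments)

    def prom(self, timepoint: Timepoint) -> Optional[PromAssessment]:
        for a in self.prom_assessments:
            if a.timepoint == timepoint:
                return a
        return None


@dataclass(frozen=True, slots=True)
class ServiceClaim:
    patient_id: str
    case_number: str
    service_date: dt.date
    case_type: CaseType
    admitting_unit: str
    executing_unit: str
    service_text: str
    service_type: str = ""
    quantity: float = 1.0


@dataclass(frozen=True, slots=True)
class CostRecord:
    # No patient identifier exists on cost lines; the case number is the
    # only link back to a patient, via the service dataset.
    case_number: str
    cost_amount: Decimal
    billing_month: int
    billing_year: int
    cost_centre_type: str

    def __post_init__(self):
        if not 1 <= self.billing_month <= 12:
            raise ValueError(f"billing month {self.billing_month} outside 1..12")


@dataclass(slots=True)
class GroupedCase:
    """One line of the 'grouped dataset' produced by merge step 1.

    The grouped dataset has one row per case number with the first and
    last billed service date, the total cost of the case and the set of
    organisational units; the underlying ungrouped claims are retained
    because step 2's search queries need claim-level text.
    """

    case_number: str
    patient_id: str
    first_service_date: dt.date
    last_service_date: dt.date
    total_cost: Decimal
    case_type: CaseType
    org_units: frozenset[str]
    claims: tuple[ServiceClaim, ...]
    cost_lines: tuple[CostRecord, ...]
    # attached from the clinical dataset by attach_clinical_dates
    treatments: tuple[TreatmentEpisode, ...] = ()
    complications: tuple[Complication, ...] = ()
    prom_dates: tuple[dt.date, ...] = ()
    death_in_hospital: bool = False

    def span_days(self) -> int:
        """Inclusive day count of the case span (single-day case -> 1)."""
        return (self.last_service_date - self.first_service_date).days + 1


@dataclass(frozen=True, slots=True)
class CategoryShare:
    category: str  # a Modality value, "diagnosis", "other" or "death_in_hospital"
    cost_share: Decimal
    evidence: tuple[str, ...] = ()


@dataclass(slots=True)
class CaseAssignment:
    """Merge step 2 output: a case represented by one line per category.

    The shares always sum exactly to the case total; a case with no rule
    match falls back to "diagnosis" (before first treatment start) or
    "other" (comorbidity care / unassignable).
    """

    case_number: str
    patient_id: str
    case_type: CaseType
    first_service_date: dt.date
    last_service_date: dt.date
    total_cost: Decimal
    shares: list[CategoryShare]

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(s.category for s in self.shares)

    def share_of(self, category: str) -> Decimal:
        return sum(
            (s.cost_share for s in self.shares if s.category == category),
            Decimal("0.00"),
        )
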