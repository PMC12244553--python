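"""Merge step 1: follow-up windowing and reduction to the grouped dataset.

Cost lines carry billing dates that can lag the underlying service by
months, so follow-up membership is decided on the *service* side: a case
number is kept when its first service date falls inside the half-open
window ``[diagnosis - lookback, diagnosis + fu_days)``, and then all of
its cost lines are kept with it.  A case that starts inside the window
and runs past its end is kept in full — costs are summed per case and
never prorated at the follow-up boundary.

The result of this step is the grouped dataset: one line per case
number with the first/last billed service date, the exact summed cost,
case type and organisational units, plus the patient's clinical dates
(treatment episodes, complications, PROM time points) attached via the
patient identifier.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import defaultdict
from decimal import Decimal

from .records import (
    CostRecord,
    GroupedCase,
    PatientClinicalRecord,
    ServiceClaim,
)

log = logging.getLogger(__name__)

DEFAULT_FU_DAYS = 365
DEFAULT_LOOKBACK_DAYS = 14


class LinkageError(ValueError):
    """A service claim references a patient missing from the clinical data."""


def restrict_to_followup(
    service: list[ServiceClaim],
    costs: list[CostRecord],
    clinical: list[PatientClinicalRecord],
    fu_days: int = DEFAULT_FU_DAYS,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> tuple[list[ServiceClaim], list[CostRecord]]:
    """Keep only case numbers whose first service date is inside the window.

    Claims of patients absent from ``clinical`` (e.g. excluded from the
    FAS) are dropped here as well.  A kept case keeps *all* its cost
    lines: cost lines have no service date of their own, and billing
    dates cannot be used for windowing.
    """
    diagnosis = {r.patient_id: r.diagnosis_date for r in clinical}

    first_date: dict[str, dt.date] = {}
    case_patient: dict[str, str] = {}
    for claim in service:
        prev = first_date.get(claim.case_number)
        if prev is None or claim.service_date < prev:
            first_date[claim.case_number] = claim.service_date
        case_patient[claim.case_number] = claim.patient_id

    kept_cases: set[str] = set()
    for case, start in first_date.items():
        pid = case_patient[case]
        if pid not in diagnosis:
            continue
        d0 = diagnosis[pid]
        lo = d0 - dt.timedelta(days=lookback_days)
        hi = d0 + dt.timedelta(days=fu_days)
        if lo <= start < hi:
            kept_cases.add(case)
        else:
            log.debug(
                "patient %s: case %s first-dated %s outside [%s, %s), dropped",
                pid, case, start, lo, hi,
            )

    kept_service = [c for c in service if c.case_number in kept_cases]
    kept_costs = [c for c in costs if c.case_number in kept_cases]
    return kept_service, kept_costs


def group_cases(
    service: list[ServiceClaim],
    costs: list[CostRecord],
    *,
    strict_orphans: bool = False,
) -> list[GroupedCase]:
    """Reduce to one :class:`GroupedCase` per case number.

    Total cost is the exact decimal sum of the case's cost lines;
    organisational units are the union of admitting and executing units.
    Cost lines whose case number has no service claim cannot be linked
    to a patient; they are excluded with a warning (or raise when
    ``strict_orphans``).
    """
    claims_by_case: dict[str, list[ServiceClaim]] = defaultdict(list)
    for claim in service:
        claims_by_case[claim.case_number].append(claim)

    costs_by_case: dict[str, list[CostRecord]] = defaultdict(list)
    orphans: set[str] = set()
    for cost in costs:
        if cost.case_number in claims_by_case:
            costs_by_case[cost.case_number].append(cost)
        else:
            orphans.add(cost.case_number)
    if orphans:
        msg = f"{len(orphans)} orphan cost case number(s) excluded: {sorted(orphans)[:5]}"
        if strict_orphans:
            raise ValueError(msg)
        log.warning(msg)

    grouped: list[GroupedCase] = []
    for case in sorted(claims_by_case):
        claims = sorted(claims_by_case[case], key=lambda c: (c.service_date, c.service_text))
        case_costs = costs_by_case.get(case, [])
        total = sum((c.cost_amount for c in case_costs), Decimal("0.00"))
        units = frozenset(
            u for c in claims for u in (c.admitting_unit, c.executing_unit) if u
        )
        grouped.append(
            GroupedCase(
                case_number=case,
                patient_id=claims[0].patient_id,
                first_service_date=min(c.service_date for c in claims),
                last_service_date=max(c.service_date for c in claims),
                total_cost=total,
                case_type=claims[0].case_type,
                org_units=units,
                claims=tuple(claims),
                cost_lines=tuple(case_costs),
            )
        )
    return grouped


def attach_clinical_dates(
    grouped: list[GroupedCase],
    clinical: list[PatientClinicalRecord],
) -> list[GroupedCase]:
    """Attach each patient's episode, complication and PROM dates in place.

    Raises :class:`LinkageError` when a grouped case references a
    patient that the clinical dataset does not know — that is a linkage
    failure, not a row-level nuisance.
    """
    by_id = {r.patient_id: r for r in clinical}
    for case in grouped:
        rec = by_id.get(case.patient_id)
        if rec is None:
            raise LinkageError(
                f"case {case.case_number!r} references patient "
                f"{case.patient_id!r} absent from the clinical dataset"
            )
        case.treatments = tuple(rec.treatments)
        case.complications = tuple(rec.complications)
        case.prom_dates = tuple(
            a.assessment_date for a in rec.prom_assessments
        )
        case.death_in_hospital = rec.death_in_hospital
    return grouped


def merge_step1(
    clinical: list[PatientClinicalRecord],
    service: list[ServiceClaim],
    costs: list[CostRecord],
    fu_days: int = DEFAULT_FU_DAYS,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> list[GroupedCase]:
    """Convenience wrapper: window, group and attach in one call."""
    service_w, costs_w = restrict_to_followup(
        service, costs, clinical, fu_days=fu_days, lookback_days=lookback_days
    )
    grouped = group_cases(service_w, costs_w)
    return attach_clinical_dates(grouped, clinical)
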