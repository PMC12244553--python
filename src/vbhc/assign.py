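"""Merge step 2: assign grouped cases to treatment categories and split costs.

A case number does not state which overarching treatment it billed.  The
engine therefore combines two kinds of evidence:

* targeted search queries over the *ungrouped* claims — drug-name tokens
  in the service text identify systemic therapies (chemotherapy,
  immunotherapy, targeted therapy), organisational-unit and DRG-text
  patterns identify surgery and radiotherapy, and a case-type
  requirement encodes constraints such as "surgery implies an inpatient
  stay";
* clinical treatment episode dates — a weak (unit/DRG) match only counts
  when the case span overlaps an episode of that modality within a small
  tolerance.  A drug-name match is strong evidence on its own and
  assigns the whole case to that systemic therapy unless further
  matches co-assign it.

Cases with no match are "diagnosis" when dated before the patient's
first treatment start, otherwise "other" (comorbidity care and
unassignable follow-up).  When the patient died in hospital, the
category "death in hospital" is put on their last case.

When several categories share one case, its summed cost is broken down
in three tiers: (1) drug-attributable costs accrue to the matched
systemic therapy, (2) radiotherapy-query costs accrue to radiotherapy,
(3) the remainder is split equally among all assigned categories.  The
shares always sum exactly to the case total (decimal arithmetic; any
odd cent from the equal division goes to the lexicographically first
category).
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from pathlib import Path
from typing import Optional

import yaml

from .ledger import GroundTruthLedger
from .records import (
    CATEGORY_DEATH,
    CATEGORY_DIAGNOSIS,
    CATEGORY_OTHER,
    SYSTEMIC_MODALITIES,
    CaseAssignment,
    CaseType,
    CategoryShare,
    GroupedCase,
    Modality,
    PatientClinicalRecord,
    chf,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModalityRule:
    modality: Modality
    drug_names: tuple[str, ...] = ()
    unit_patterns: tuple[str, ...] = ()
    drg_text_patterns: tuple[str, ...] = ()
    required_case_type: Optional[CaseType] = None
    date_overlap_required: bool = False
    tolerance_days: int = 7


@dataclass
class AssignmentRuleSet:
    rules: dict[Modality, ModalityRule]
    #: configured unit price per drug token, used to attribute tier-1 drug
    #: costs when cost lines cannot be traced to individual claims (case-level
    #: cost data).  An empty mapping means tier 1 attributes nothing and the
    #: whole remainder is split equally (tier 3), with a logged warning.
    drug_unit_costs: dict[str, Decimal] = field(default_factory=dict)
    #: cost-centre-type patterns identifying radiotherapy cost lines (tier 2)
    radio_cost_centre_patterns: tuple[str, ...] = ("radio",)

    def __post_init__(self):
        if not self.rules:
            raise ValueError("rule set enables zero modalities")
        for m, r in self.rules.items():
            if not (r.drug_names or r.unit_patterns or r.drg_text_patterns):
                raise ValueError(f"rule for {m.value} has no patterns at all")

    def drug_modality(self, token: str) -> Optional[Modality]:
        for m, r in self.rules.items():
            if token in r.drug_names:
                return m
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssignmentRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = {}
        for name, spec in raw.get("modalities", {}).items():
            m = Modality(name)
            rules[m] = ModalityRule(
                modality=m,
                drug_names=tuple(t.lower() for t in spec.get("drug_names", [])),
                unit_patterns=tuple(t.lower() for t in spec.get("unit_patterns", [])),
                drg_text_patterns=tuple(
                    t.lower() for t in spec.get("drg_text_patterns", [])
                ),
                required_case_type=(
                    CaseType(spec["required_case_type"])
                    if spec.get("required_case_type")
                    else None
                ),
                date_overlap_required=bool(spec.get("date_overlap_required", False)),
                tolerance_days=int(spec.get("tolerance_days", 7)),
            )
        unit_costs = {
            k.lower(): chf(v) for k, v in raw.get("drug_unit_costs", {}).items()
        }
        return cls(
            rules=rules,
            drug_unit_costs=unit_costs,
            radio_cost_centre_patterns=tuple(
                t.lower() for t in raw.get("radio_cost_centre_patterns", ["radio"])
            ),
        )


@dataclass
class MatchResult:
    evidence: tuple[str, ...]
    #: (claim index, token, quantity) for drug matches, for tier-1 attribution
    drug_hits: tuple[tuple[int, str, float], ...] = ()


def _spans_overlap(a_start, a_end, b_start, b_end, tolerance_days: int) -> bool:
    pad = dt.timedelta(days=tolerance_days)
    return a_start - pad <= b_end and a_end + pad >= b_start


def _match_rule(case: GroupedCase, rule: ModalityRule) -> Optional[MatchResult]:
    if rule.required_case_type is not None and case.case_type != rule.required_case_type:
        return None
    evidence: list[str] = []
    drug_hits: list[tuple[int, str, float]] = []
    for i, claim in enumerate(case.claims):
        text = claim.service_text.lower()
        for token in rule.drug_names:
            if token in text:
                evidence.append(f"drug:{token}")
                drug_hits.append((i, token, claim.quantity))
        for pattern in rule.drg_text_patterns:
            if pattern in text:
                evidence.append(f"drg:{pattern}")
    lowered_units = [u.lower() for u in case.org_units]
    for pattern in rule.unit_patterns:
        if any(pattern in u for u in lowered_units):
            evidence.append(f"unit:{pattern}")
    if not evidence:
        return None
    if rule.date_overlap_required:
        episodes = [ep for ep in case.treatments if ep.modality == rule.modality]
        if not any(
            _spans_overlap(
                case.first_service_date,
                case.last_service_date,
                ep.start_date,
                ep.end_date,
                rule.tolerance_days,
            )
            for ep in episodes
        ):
            return None
    return MatchResult(evidence=tuple(dict.fromkeys(evidence)), drug_hits=tuple(drug_hits))


def match_case(
    case: GroupedCase, rules: AssignmentRuleSet
) -> dict[Modality, MatchResult]:
    """Evaluate every modality rule against one grouped case."""
    matches: dict[Modality, MatchResult] = {}
    for modality, rule in rules.rules.items():
        result = _match_rule(case, rule)
        if result is not None:
            matches[modality] = result
    return matches


def split_case_costs(
    case: GroupedCase,
    categories: dict[str, tuple[str, ...]],
    rules: AssignmentRuleSet,
    drug_matches: dict[Modality, MatchResult] | None = None,
) -> CaseAssignment:
    """Break the case total down into per-category shares (three tiers).

    ``categories`` maps each assigned category to its evidence.  Raises
    when tier-1 + tier-2 attribution exceeds the case total — that
    indicates corrupted input, not a rounding issue.
    """
    if not categories:
        raise ValueError(f"case {case.case_number}: no categories to split over")
    names = sorted(categories)
    total = chf(case.total_cost)

    if len(names) == 1:
        return CaseAssignment(
            case_number=case.case_number,
            patient_id=case.patient_id,
            case_type=case.case_type,
            first_service_date=case.first_service_date,
            last_service_date=case.last_service_date,
            total_cost=total,
            shares=[CategoryShare(names[0], total, categories[names[0]])],
        )

    drug_matches = drug_matches or {}
    attributed: dict[str, Decimal] = {name: Decimal("0.00") for name in names}

    # tier 1: drug-attributable costs per matched systemic therapy
    for modality, match in drug_matches.items():
        if modality.value not in categories or modality not in SYSTEMIC_MODALITIES:
            continue
        for _idx, token, quantity in match.drug_hits:
            unit = rules.drug_unit_costs.get(token)
            if unit is None:
                log.warning(
                    "case %s: no unit cost configured for drug %r; its cost "
                    "falls through to the equal split",
                    case.case_number, token,
                )
                continue
            attributed[modality.value] += chf(unit * Decimal(str(quantity)))

    # tier 2: radiotherapy-query cost lines
    if Modality.RADIOTHERAPY.value in categories:
        for line in case.cost_lines:
            centre = line.cost_centre_type.lower()
            if any(p in centre for p in rules.radio_cost_centre_patterns):
                attributed[Modality.RADIOTHERAPY.value] += line.cost_amount

    residual = total - sum(attributed.values(), Decimal("0.00"))
    if residual < 0:
        raise ValueError(
            f"case {case.case_number}: attributed components "
            f"{total - residual} exceed case total {total}"
        )

    # tier 3: equal split of the residual; odd cents to the first category
    n = len(names)
    base = (residual / n).quantize(Decimal("0.01"), rounding=ROUND_DOWN)
    remainder = residual - base * n
    shares = []
    for i, name in enumerate(names):
        amount = attributed[name] + base + (remainder if i == 0 else Decimal("0.00"))
        shares.append(CategoryShare(name, chf(amount), categories[name]))
    return CaseAssignment(
        case_number=case.case_number,
        patient_id=case.patient_id,
        case_type=case.case_type,
        first_service_date=case.first_service_date,
        last_service_date=case.last_service_date,
        total_cost=total,
        shares=shares,
    )


def assign_categories(
    grouped: list[GroupedCase],
    rules: AssignmentRuleSet,
) -> list[CaseAssignment]:
    """Assign every grouped case to one or more categories and split costs."""
    # the death-in-hospital category goes on the patient's last case
    last_case: dict[str, str] = {}
    last_key: dict[str, tuple] = {}
    for case in grouped:
        key = (case.last_service_date, case.case_number)
        if case.patient_id not in last_key or key > last_key[case.patient_id]:
            last_key[case.patient_id] = key
            last_case[case.patient_id] = case.case_number

    assignments: list[CaseAssignment] = []
    for case in grouped:
        matches = match_case(case, rules)
        categories: dict[str, tuple[str, ...]] = {
            m.value: res.evidence for m, res in matches.items()
        }
        if case.death_in_hospital and last_case.get(case.patient_id) == case.case_number:
            categories[CATEGORY_DEATH] = ("clinical:death_in_hospital",)
        if not categories:
            first_tx = min(
                (ep.start_date for ep in case.treatments), default=None
            )
            if first_tx is None or case.first_service_date < first_tx:
                categories[CATEGORY_DIAGNOSIS] = ("fallback:before_first_treatment",)
            else:
                categories[CATEGORY_OTHER] = ("fallback:unassigned",)
        assignments.append(split_case_costs(case, categories, rules, matches))
    return assignments


# ---------------------------------------------------------------------------
# validation against the clinical record and (synthetic only) the ledger


@dataclass
class ModalityAllocation:
    modality: str
    n_patients_with_episode: int
    n_patients_allocated: int

    @property
    def allocation_rate(self) -> Optional[float]:
        if self.n_patients_with_episode == 0:
            return None
        return 100.0 * self.n_patients_allocated / self.n_patients_with_episode


@dataclass
class AllocationReport:
    by_modality: dict[str, ModalityAllocation]
    n_cases: int = 0
    #: ledger comparison (None when no ledger was supplied)
    n_cases_in_ledger: Optional[int] = None
    n_cases_category_exact: Optional[int] = None
    n_patient_totals: Optional[int] = None
    n_patient_totals_exact: Optional[int] = None
    max_patient_total_error: Optional[Decimal] = None

    @property
    def category_recovery_rate(self) -> Optional[float]:
        if not self.n_cases_in_ledger:
            return None
        return 100.0 * self.n_cases_category_exact / self.n_cases_in_ledger


def validate_allocation(
    assignments: list[CaseAssignment],
    clinical: list[PatientClinicalRecord],
    ledger: GroundTruthLedger | None = None,
) -> AllocationReport:
    """Compare assigned cases against clinically recorded treatments.

    The per-modality allocation rate is the share of patients with at
    least one recorded episode of a modality for whom at least one case
    was assigned to it.  With a synthetic ledger, per-case category sets
    and per-(patient, category) cost totals are additionally scored
    against the ground truth.
    """
    assigned_by_patient: dict[str, set[str]] = defaultdict(set)
    for a in assignments:
        assigned_by_patient[a.patient_id] |= a.categories

    by_modality: dict[str, ModalityAllocation] = {}
    for modality in Modality:
        with_ep = [
            r.patient_id
            for r in clinical
            if any(ep.modality == modality for ep in r.treatments)
        ]
        allocated = [
            pid for pid in with_ep if modality.value in assigned_by_patient.get(pid, set())
        ]
        by_modality[modality.value] = ModalityAllocation(
            modality=modality.value,
            n_patients_with_episode=len(with_ep),
            n_patients_allocated=len(allocated),
        )

    report = AllocationReport(by_modality=by_modality, n_cases=len(assignments))
    if ledger is None:
        return report

    clinical_ids = {r.patient_id for r in clinical}
    in_ledger = [a for a in assignments if a.case_number in ledger.entries]
    exact = sum(
        1
        for a in in_ledger
        if a.categories == ledger.entries[a.case_number].categories
    )
    report.n_cases_in_ledger = len(in_ledger)
    report.n_cases_category_exact = exact

    pipeline_totals: dict[tuple[str, str], Decimal] = defaultdict(lambda: Decimal("0.00"))
    for a in assignments:
        for s in a.shares:
            pipeline_totals[(a.patient_id, s.category)] += s.cost_share
    # ledger entries of patients outside the supplied cohort (e.g. excluded
    # from the FAS before the merge) are not part of the comparison
    truth = {
        k: v
        for k, v in ledger.patient_category_totals().items()
        if k[0] in clinical_ids
    }
    keys = set(truth) | set(pipeline_totals)
    errors = [
        abs(pipeline_totals.get(k, Decimal("0.00")) - truth.get(k, Decimal("0.00")))
        for k in keys
    ]
    report.n_patient_totals = len(keys)
    report.n_patient_totals_exact = sum(1 for e in errors if e == 0)
    report.max_patient_total_error = max(errors, default=Decimal("0.00"))
    return report


def patient_category_totals(
    assignments: list[CaseAssignment],
) -> dict[tuple[str, str], Decimal]:
    """Total assigned cost per (patient_id, category)."""
    totals: dict[tuple[str, str], Decimal] = defaultdict(lambda: Decimal("0.00"))
    for a in assignments:
        for s in a.shares:
            totals[(a.patient_id, s.category)] += s.cost_share
    return dict(totals)
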