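"""Structural consistency checks across the three datasets.

The merge is only as good as the key material shared between datasets,
so before any linkage we enumerate the ways the keys can disagree:
cost lines whose case number never appears in the service dataset
(orphan costs — unlinkable to any patient), service cases that never
accrue a cost line, patients present in one dataset but not the other,
and case numbers that violate the one-patient / one-case-type rule.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .records import CostRecord, PatientClinicalRecord, ServiceClaim


@dataclass
class ValidationReport:
    orphan_cost_cases: list[str] = field(default_factory=list)
    uncosted_service_cases: list[str] = field(default_factory=list)
    unmatched_patients: list[str] = field(default_factory=list)
    inconsistent_cases: list[str] = field(default_factory=list)

    @property
    def n_findings(self) -> int:
        return (
            len(self.orphan_cost_cases)
            + len(self.uncosted_service_cases)
            + len(self.unmatched_patients)
            + len(self.inconsistent_cases)
        )

    def is_clean(self) -> bool:
        return self.n_findings == 0

    def summary(self) -> str:
        return (
            f"orphan cost cases: {len(self.orphan_cost_cases)}; "
            f"uncosted service cases: {len(self.uncosted_service_cases)}; "
            f"unmatched patients: {len(self.unmatched_patients)}; "
            f"inconsistent cases: {len(self.inconsistent_cases)}"
        )


def validate_consistency(
    clinical: list[PatientClinicalRecord],
    service: list[ServiceClaim],
    costs: list[CostRecord],
) -> ValidationReport:
    """Report key inconsistencies between the three datasets.

    This is a reporting operation: it never raises.  Downstream steps
    decide how to treat each finding (e.g. orphan cost cases are
    excluded from grouping with a warning).
    """
    report = ValidationReport()

    service_cases = {c.case_number for c in service}
    cost_cases = {c.case_number for c in costs}
    report.orphan_cost_cases = sorted(cost_cases - service_cases)
    report.uncosted_service_cases = sorted(service_cases - cost_cases)

    clinical_patients = {r.patient_id for r in clinical}
    service_patients = {c.patient_id for c in service}
    report.unmatched_patients = sorted(
        (service_patients - clinical_patients) | (clinical_patients - service_patients)
    )

    owners: dict[str, set] = defaultdict(set)
    for claim in service:
        owners[claim.case_number].add((claim.patient_id, claim.case_type))
    report.inconsistent_cases = sorted(
        case for case, keys in owners.items() if len(keys) > 1
    )
    return report
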