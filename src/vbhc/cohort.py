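"""Cohort eligibility filtering and follow-up status accounting.

The full analysis set (FAS) excludes patients concurrently enrolled in
clinical trials (services covered by trial budgets may not appear in
hospital accounting) and patients resident in regions whose care is
split across hospitals (only part of their services shows up locally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import PatientClinicalRecord, VitalStatus


@dataclass
class CohortFilterReport:
    n_enrolled: int
    n_excluded_trial: int
    n_excluded_region: int
    n_excluded_both: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (patient_id, reason)

    @property
    def n_fas(self) -> int:
        return (
            self.n_enrolled
            - self.n_excluded_trial
            - self.n_excluded_region
            - self.n_excluded_both
        )

    @property
    def fas_share(self) -> float:
        """FAS size as a percentage of enrolment."""
        return 100.0 * self.n_fas / self.n_enrolled if self.n_enrolled else 0.0


def filter_eligible(
    clinical: list[PatientClinicalRecord],
    excluded_regions: frozenset[str] | set[str],
) -> tuple[list[PatientClinicalRecord], CohortFilterReport]:
    """Derive the FAS: drop trial participants and out-of-region patients.

    The report partitions exclusions into trial-only, region-only and
    both, so that ``n_fas = n_enrolled - trial - region - both``.
    Idempotent: re-filtering the FAS removes nobody.
    """
    excluded_regions = frozenset(excluded_regions)
    fas: list[PatientClinicalRecord] = []
    n_trial = n_region = n_both = 0
    exclusions: list[tuple[str, str]] = []
    for rec in clinical:
        trial = rec.trial_participant
        region = rec.residency_region in excluded_regions
        if trial and region:
            n_both += 1
            exclusions.append((rec.patient_id, "trial+region"))
        elif trial:
            n_trial += 1
            exclusions.append((rec.patient_id, "trial"))
        elif region:
            n_region += 1
            exclusions.append((rec.patient_id, "region"))
        else:
            fas.append(rec)
    report = CohortFilterReport(
        n_enrolled=len(clinical),
        n_excluded_trial=n_trial,
        n_excluded_region=n_region,
        n_excluded_both=n_both,
        exclusions=exclusions,
    )
    return fas, report


@dataclass
class StatusReport:
    n_patients: int
    n_alive: int
    n_dead: int
    n_deactivated: int
    n_death_in_hospital: int
    deactivation_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_discontinued(self) -> int:
        """Patients who did not complete follow-up (dead or deactivated)."""
        return self.n_dead + self.n_deactivated

    @property
    def discontinued_share(self) -> float:
        return 100.0 * self.n_discontinued / self.n_patients if self.n_patients else 0.0


def summarize_status(clinical: list[PatientClinicalRecord]) -> StatusReport:
    """Count vital / deactivation status at the analysis cut-off."""
    reasons: dict[str, int] = {}
    n_alive = n_dead = n_deact = n_dih = 0
    for rec in clinical:
        if rec.vital_status is VitalStatus.DEAD:
            n_dead += 1
            if rec.death_in_hospital:
                n_dih += 1
        elif rec.vital_status is VitalStatus.DEACTIVATED:
            n_deact += 1
            reason = rec.deactivation_reason or "unspecified"
            reasons[reason] = reasons.get(reason, 0) + 1
        else:
            n_alive += 1
    return StatusReport(
        n_patients=len(clinical),
        n_alive=n_alive,
        n_dead=n_dead,
        n_deactivated=n_deact,
        n_death_in_hospital=n_dih,
        deactivation_reasons=reasons,
    )
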