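import datetime as dt
from decimal import Decimal

import pytest

from vbhc.config import default_rules
from vbhc.records import (
    CaseType,
    Comorbidity,
    CostRecord,
    GroupedCase,
    Histology,
    PatientClinicalRecord,
    ServiceClaim,
    Sex,
    Smoking,
    Stage,
    VitalStatus,
    chf,
)
from vbhc.simulate import GeneratorConfig, generate

D0 = dt.date(2021, 3, 1)


def make_patient(pid="P1", diagnosis=D0, **overrides) -> PatientClinicalRecord:
    defaults = dict(
        patient_id=pid,
        diagnosis_date=diagnosis,
        histology=Histology.ADENOCARCINOMA,
        stage=Stage.II,
        sex=Sex.FEMALE,
        age_at_diagnosis=68,
        comorbidity_category=Comorbidity.MODERATE,
        smoking_status=Smoking.EX,
        trial_participant=False,
        residency_region="BS",
        vital_status=VitalStatus.ALIVE,
        status_date=diagnosis + dt.timedelta(days=365),
    )
    defaults.update(overrides)
    return PatientClinicalRecord(**defaults)


def make_claim(pid="P1", case="K1", date=D0, case_type=CaseType.OUTPATIENT,
               text="consultation", unit="oncology outpatient clinic",
               quantity=1.0) -> ServiceClaim:
    return ServiceClaim(
        patient_id=pid, case_number=case, service_date=date,
        case_type=case_type, admitting_unit=unit, executing_unit=unit,
        service_text=text, service_type="", quantity=quantity,
    )


def make_cost(case="K1", amount="1000.00", month=4, year=2021,
              centre="ward") -> CostRecord:
    return CostRecord(case_number=case, cost_amount=chf(amount),
                      billing_month=month, billing_year=year,
                      cost_centre_type=centre)


def make_grouped(case="K1", pid="P1", first=D0, last=None, total="1000.00",
                 case_type=CaseType.OUTPATIENT, claims=(), cost_lines=(),
                 org_units=frozenset(), treatments=(),
                 death_in_hospital=False) -> GroupedCase:
    return GroupedCase(
        case_number=case, patient_id=pid, first_service_date=first,
        last_service_date=last or first, total_cost=chf(total),
        case_type=case_type, org_units=frozenset(org_units),
        claims=tuple(claims), cost_lines=tuple(cost_lines),
        treatments=tuple(treatments), death_in_hospital=death_in_hospital,
    )


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient fully consistent synthetic cohort, fixed seed."""
    return generate(GeneratorConfig(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_cohort):
    from vbhc.simulate import write_datasets

    directory = tmp_path_factory.mktemp("datasets")
    write_datasets(*small_cohort, directory)
    return directory
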