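"""Seeded synthetic hospital-data generator with a ground-truth ledger.

No public dataset couples Swiss clinical records, service claims and
REKOLE cost accounting, so the pipeline is exercised on a generator
that emulates the structural constraints of those systems:

* every patient has one identifier and several case numbers; inpatient
  and outpatient claims never share a case number;
* a diagnostic work-up case precedes the first treatment; each surgery
  is one inpatient case; systemic-therapy courses are outpatient cases
  whose service text carries drug names; radiotherapy cases carry a
  radio-oncology executing unit; comorbidity care appears as unrelated
  "other" cases; in-hospital death produces a terminal inpatient case;
* an inpatient case number is reused only for a readmission within 18
  days of the previous discharge;
* cost lines are keyed by case number only and their billing month lags
  the last service date by 0-3 months;
* drugs are billed at exact list prices (unit price x quantity), while
  ward / clinic / theatre residuals are right-skewed (log-normal,
  parameterised by median and dispersion).

Every case is recorded in a :class:`~vbhc.ledger.GroundTruthLedger`
with its true category set and exact cost decomposition, which is what
downstream recovery tests score against.  Inconsistencies seen in real
data (unidentifiable drug text, externally purchased targeted drugs,
orphan cost lines) can be injected at configurable rates; the injection
uses one uniform draw per case and decision so that runs at different
rates under the same seed are coupled (a case corrupted at rate 0.25 is
still corrupted at rate 0.5), which makes sensitivity sweeps monotone
by construction.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from decimal import Decimal
from pathlib import Path

import numpy as np
import yaml

from . import config as cfg
from .ledger import GroundTruthLedger, LedgerEntry
from .records import (
    CATEGORY_DEATH,
    CATEGORY_DIAGNOSIS,
    CATEGORY_OTHER,
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


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CostModel:
    """Right-skewed case-cost model: log-normal with stated median."""

    median: Decimal
    sigma: float
    drug_fraction: float = 0.0  # target share billed as exact-priced drug lines


@dataclass(frozen=True)
class PromModel:
    baseline_mean: float = 65.0
    baseline_sd: float = 15.0
    visit_sd: float = 6.0
    baseline_missing_rate: float = 0.08
    missing_rate: float = 0.15
    stage_drift: dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.I: 1.0, Stage.II: 0.0, Stage.III: -2.0,
            Stage.IV: -6.0, Stage.UNKNOWN: -3.0,
        }
    )
    modality_drift: dict[Modality, float] = field(
        default_factory=lambda: {
            Modality.SURGERY: -6.0,
            Modality.CHEMOTHERAPY: -5.0,
            Modality.RADIOTHERAPY: -3.0,
            Modality.IMMUNOTHERAPY: -2.0,
            Modality.TARGETED_THERAPY: -2.0,
        }
    )


@dataclass(frozen=True)
class InconsistencyRates:
    blank_drug: float = 0.0
    external_pharmacy: float = 0.0
    orphan_cost: float = 0.0


@dataclass(frozen=True)
class ExclusionRates:
    trial: float = 0.215
    out_of_region: float = 0.0785


TreatmentPolicy = dict[Stage, list[tuple[tuple[Modality, ...], float]]]


def _default_policy() -> TreatmentPolicy:
    S, C, R, I, T = (
        Modality.SURGERY,
        Modality.CHEMOTHERAPY,
        Modality.RADIOTHERAPY,
        Modality.IMMUNOTHERAPY,
        Modality.TARGETED_THERAPY,
    )
    return {
        Stage.I: [((S,), 0.70), ((S, C), 0.10), ((R,), 0.20)],
        Stage.II: [((S, C), 0.50), ((S,), 0.30), ((C, R), 0.20)],
        Stage.III: [((S, C, R), 0.25), ((C, R), 0.45), ((C, I), 0.30)],
        Stage.IV: [
            ((C, I), 0.40), ((I,), 0.20), ((C, R), 0.15),
            ((T,), 0.15), ((C,), 0.10),
        ],
    }


def _default_cost_model() -> dict[str, CostModel]:
    return {
        Modality.SURGERY.value: CostModel(Decimal("40000"), 0.55),
        Modality.CHEMOTHERAPY.value: CostModel(Decimal("13000"), 0.60, 0.45),
        Modality.RADIOTHERAPY.value: CostModel(Decimal("17000"), 0.60),
        Modality.IMMUNOTHERAPY.value: CostModel(Decimal("45000"), 0.55, 0.72),
        Modality.TARGETED_THERAPY.value: CostModel(Decimal("31500"), 0.45, 0.70),
        CATEGORY_DIAGNOSIS: CostModel(Decimal("12000"), 0.70),
        CATEGORY_OTHER: CostModel(Decimal("8000"), 0.90),
        CATEGORY_DEATH: CostModel(Decimal("31000"), 0.60),
    }


@dataclass
class GeneratorConfig:
    n_patients: int = 200
    seed: int = 0
    fu_days: int = 365
    enrollment_start: dt.date = dt.date(2021, 1, 4)
    enrollment_days: int = 540
    stage_distribution: dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.I: 0.43, Stage.II: 0.12, Stage.III: 0.16, Stage.IV: 0.29,
        }
    )
    histology_distribution: dict[Histology, float] = field(
        default_factory=lambda: {
            Histology.ADENOCARCINOMA: 0.63,
            Histology.SQUAMOUS_CELL: 0.20,
            Histology.SMALL_CELL: 0.08,
            Histology.NSCLC_OTHER: 0.06,
            Histology.OTHER: 0.03,
        }
    )
    treatment_policy: TreatmentPolicy = field(default_factory=_default_policy)
    cost_model: dict[str, CostModel] = field(default_factory=_default_cost_model)
    prom_model: PromModel = field(default_factory=PromModel)
    inconsistency_rates: InconsistencyRates = field(default_factory=InconsistencyRates)
    exclusion_rates: ExclusionRates = field(default_factory=ExclusionRates)
    #: probability of death within follow-up, by stage
    death_rates: dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.I: 0.05, Stage.II: 0.10, Stage.III: 0.22,
            Stage.IV: 0.40, Stage.UNKNOWN: 0.20,
        }
    )
    death_in_hospital_share: float = 1 / 3
    deactivation_rate: float = 0.18
    comorbidity_case_rate: float = 0.55
    readmission_rate: float = 0.10
    male_share: float = 0.61
    excluded_region: str = "JU"
    home_regions: tuple[str, ...] = ("BS", "BL", "SO", "AG")

    def __post_init__(self):
        for name, dist in (
            ("stage_distribution", self.stage_distribution),
            ("histology_distribution", self.histology_distribution),
        ):
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError(f"{name} sums to {total}, expected 1")
        for stage, options in self.treatment_policy.items():
            total = sum(p for _, p in options)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError(
                    f"treatment_policy[{stage.value}] sums to {total}, expected 1"
                )
        for rates in (self.inconsistency_rates, self.exclusion_rates):
            for fname in rates.__dataclass_fields__:
                v = getattr(rates, fname)
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"rate {fname}={v} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("n_patients", "seed", "fu_days", "deactivation_rate",
                    "comorbidity_case_rate", "readmission_rate", "male_share",
                    "excluded_region"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stage_distribution" in raw:
            kwargs["stage_distribution"] = {
                Stage(k): float(v) for k, v in raw["stage_distribution"].items()
            }
        if "histology_distribution" in raw:
            kwargs["histology_distribution"] = {
                Histology(k): float(v) for k, v in raw["histology_distribution"].items()
            }
        if "cost_model" in raw:
            kwargs["cost_model"] = {
                k: CostModel(
                    median=Decimal(str(v["median"])),
                    sigma=float(v.get("sigma", 0.6)),
                    drug_fraction=float(v.get("drug_fraction", 0.0)),
                )
                for k, v in raw["cost_model"].items()
            }
        if "inconsistency_rates" in raw:
            kwargs["inconsistency_rates"] = InconsistencyRates(**raw["inconsistency_rates"])
        if "exclusion_rates" in raw:
            kwargs["exclusion_rates"] = ExclusionRates(**raw["exclusion_rates"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# helpers


def _draw_cost(rng: np.random.Generator, model: CostModel) -> Decimal:
    value = rng.lognormal(mean=math.log(float(model.median)), sigma=model.sigma)
    return chf(round(value, 2))


def _split_amount(total: Decimal, fractions: list[tuple[str, float]]) -> list[tuple[str, Decimal]]:
    """Split ``total`` into exact decimal parts; the last part absorbs rounding."""
    parts: list[tuple[str, Decimal]] = []
    running = Decimal("0.00")
    for centre, frac in fractions[:-1]:
        amount = chf(total * Decimal(str(frac)))
        parts.append((centre, amount))
        running += amount
    parts.append((fractions[-1][0], total - running))
    return parts


def _billing(rng: np.random.Generator, last_service: dt.date) -> tuple[int, int]:
    lag = int(rng.integers(0, 4))  # 0-3 months after last service
    month = last_service.month - 1 + lag
    return last_service.year + month // 12, month % 12 + 1


@dataclass
class _CaseBuild:
    case_number: str
    patient_id: str
    case_type: CaseType
    claims: list[ServiceClaim] = field(default_factory=list)
    costs: list[CostRecord] = field(default_factory=list)
    categories: frozenset[str] = frozenset()
    shares: dict[str, Decimal] = field(default_factory=dict)
    drug_components: dict[str, Decimal] = field(default_factory=dict)
    radio_component: Decimal = Decimal("0.00")


def _weighted_choice(rng: np.random.Generator, options, weights):
    idx = rng.choice(len(options), p=np.asarray(weights, dtype=float))
    return options[int(idx)]


# ---------------------------------------------------------------------------
# the generator


def generate(
    config: GeneratorConfig,
) -> tuple[list[PatientClinicalRecord], list[ServiceClaim], list[CostRecord], GroundTruthLedger]:
    """Generate the three datasets plus the ground-truth ledger.

    Fully deterministic under ``config.seed``.  Inconsistency injection
    is applied at ``config.inconsistency_rates`` as the final step (all
    zeros leaves the output untouched).
    """
    rng = np.random.default_rng(config.seed)
    clinical: list[PatientClinicalRecord] = []
    service: list[ServiceClaim] = []
    costs: list[CostRecord] = []
    ledger = GroundTruthLedger()

    stages = list(config.stage_distribution)
    stage_p = [config.stage_distribution[s] for s in stages]
    histologies = list(config.histology_distribution)
    histo_p = [config.histology_distribution[h] for h in histologies]

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        builds, record = _generate_patient(rng, config, pid, stages, stage_p,
                                           histologies, histo_p)
        clinical.append(record)
        for b in builds:
            service.extend(b.claims)
            costs.extend(b.costs)
            ledger.add(
                LedgerEntry(
                    case_number=b.case_number,
                    patient_id=b.patient_id,
                    categories=b.categories,
                    shares=b.shares,
                    drug_components=b.drug_components,
                    radiotherapy_component=b.radio_component,
                )
            )

    rates = config.inconsistency_rates
    if rates.blank_drug or rates.external_pharmacy or rates.orphan_cost:
        service, costs = inject_inconsistencies(
            service, costs, ledger, rates, seed=config.seed + 1
        )
    return clinical, service, costs, ledger


def _generate_patient(rng, config, pid, stages, stage_p, histologies, histo_p):
    d0 = config.enrollment_start + dt.timedelta(days=int(rng.integers(0, config.enrollment_days)))
    stage = _weighted_choice(rng, stages, stage_p)
    histology = _weighted_choice(rng, histologies, histo_p)
    sex = Sex.MALE if rng.random() < config.male_share else Sex.FEMALE
    age = int(np.clip(round(rng.normal(71, 10)), 35, 95))
    comorbidity = _weighted_choice(
        rng,
        [Comorbidity.NONE, Comorbidity.LOW, Comorbidity.MODERATE,
         Comorbidity.SEVERE, Comorbidity.MISSING],
        [0.24, 0.02, 0.35, 0.26, 0.13],
    )
    smoking = _weighted_choice(
        rng,
        [Smoking.NEVER, Smoking.EX, Smoking.CURRENT, Smoking.MISSING],
        [0.19, 0.34, 0.33, 0.14],
    )
    trial = bool(rng.random() < config.exclusion_rates.trial)
    if rng.random() < config.exclusion_rates.out_of_region:
        region = config.excluded_region
    else:
        region = config.home_regions[int(rng.integers(0, len(config.home_regions)))]

    # survival / follow-up disposition
    dead = bool(rng.random() < config.death_rates.get(stage, 0.2))
    death_day = int(rng.integers(60, config.fu_days)) if dead else None
    death_in_hospital = bool(dead and rng.random() < config.death_in_hospital_share)
    deact_day = None
    deact_reason = None
    if not dead and rng.random() < config.deactivation_rate:
        deact_day = int(rng.integers(30, config.fu_days))
        deact_reason = _weighted_choice(
            rng,
            ["personal concerns", "unresponsive follow-up", "health situation", "other"],
            [0.65, 0.24, 0.055, 0.055],
        )

    # treatments live inside [diagnosis + ~1-3 weeks, window_end]
    window_end_day = (death_day - 15) if dead else (config.fu_days - 1)
    policy = config.treatment_policy.get(stage) or config.treatment_policy[Stage.IV]
    sequence = _weighted_choice(rng, [seq for seq, _ in policy], [p for _, p in policy])

    case_seq = [0]

    def next_case() -> str:
        case_seq[0] += 1
        return f"K{pid[1:]}-{case_seq[0]:02d}"

    builds: list[_CaseBuild] = []
    episodes: list[TreatmentEpisode] = []
    complications: list[Complication] = []

    cursor = int(rng.integers(7, 22))
    for modality in sequence:
        if cursor > window_end_day:
            break
        start = d0 + dt.timedelta(days=cursor)
        window_end = d0 + dt.timedelta(days=window_end_day)
        if modality is Modality.SURGERY:
            build, episode, compl = _surgery_case(
                rng, config, pid, next_case(), start, window_end
            )
            if compl is not None:
                complications.append(compl)
        elif modality is Modality.RADIOTHERAPY:
            build, episode = _radiotherapy_case(
                rng, config, pid, next_case(), start, window_end
            )
        else:
            build, episode = _systemic_case(
                rng, config, pid, next_case(), modality, start, window_end
            )
        builds.append(build)
        episodes.append(episode)
        cursor = (episode.end_date - d0).days + int(rng.integers(5, 26))

    first_tx_day = min(((ep.start_date - d0).days for ep in episodes), default=None)

    # diagnostic work-up before the first treatment (always present)
    workup_last = min(first_tx_day - 4, 3) if first_tx_day is not None else 3
    builds.insert(
        0, _workup_case(rng, config, pid, f"K{pid[1:]}-00", d0, workup_last)
    )

    # comorbidity care, strictly after the first treatment start
    if episodes and rng.random() < config.comorbidity_case_rate:
        n_cases = 1 + int(rng.random() < 0.3)
        for _ in range(n_cases):
            lo = first_tx_day + 1
            if lo >= window_end_day:
                break
            day = int(rng.integers(lo, window_end_day + 1))
            builds.append(
                _comorbidity_case(
                    rng, config, pid, next_case(),
                    d0 + dt.timedelta(days=day),
                    d0 + dt.timedelta(days=window_end_day),
                )
            )

    if death_in_hospital:
        builds.append(
            _death_case(
                rng, config, pid, next_case(), d0 + dt.timedelta(days=death_day)
            )
        )

    # PROM trajectory
    proms = _generate_proms(
        rng, config, d0, stage, episodes,
        cutoff_day=min(
            d for d in (death_day, deact_day, config.fu_days) if d is not None
        ),
    )

    if dead:
        vital, status_date = VitalStatus.DEAD, d0 + dt.timedelta(days=death_day)
    elif deact_day is not None:
        vital, status_date = VitalStatus.DEACTIVATED, d0 + dt.timedelta(days=deact_day)
    else:
        vital, status_date = VitalStatus.ALIVE, d0 + dt.timedelta(days=config.fu_days)

    record = PatientClinicalRecord(
        patient_id=pid,
        diagnosis_date=d0,
        histology=histology,
        stage=stage,
        sex=sex,
        age_at_diagnosis=age,
        comorbidity_category=comorbidity,
        smoking_status=smoking,
        trial_participant=trial,
        residency_region=region,
        vital_status=vital,
        status_date=status_date,
        death_in_hospital=death_in_hospital,
        deactivation_reason=deact_reason,
        treatments=episodes,
        complications=complications,
        prom_assessments=proms,
    )
    return builds, record


def _emit_costs(rng, build, last_service, parts):
    for centre, amount in parts:
        if amount == 0:
            continue
        year, month = _billing(rng, last_service)
        build.costs.append(
            CostRecord(
                case_number=build.case_number,
                cost_amount=amount,
                billing_month=month,
                billing_year=year,
                cost_centre_type=centre,
            )
        )


def _workup_case(rng, config, pid, case, d0, last_offset):
    start = d0 - dt.timedelta(days=int(rng.integers(3, 11)))
    b = _CaseBuild(case, pid, CaseType.OUTPATIENT)
    texts = [
        ("CT thorax imaging", "radiology"),
        ("bronchoscopy with biopsy", "pneumology"),
        ("tumour board consultation", "oncology outpatient clinic"),
    ]
    n_days = (d0 + dt.timedelta(days=last_offset) - start).days
    for j, (text, unit) in enumerate(texts):
        date = start + dt.timedelta(days=min(j * max(1, n_days // 2), n_days))
        b.claims.append(
            ServiceClaim(pid, case, date, CaseType.OUTPATIENT,
                         admitting_unit=unit, executing_unit=unit,
                         service_text=text, service_type="diagnostic")
        )
    total = _draw_cost(rng, config.cost_model[CATEGORY_DIAGNOSIS])
    last = max(c.service_date for c in b.claims)
    _emit_costs(rng, b, last, _split_amount(
        total, [(cfg.CENTRE_DIAGNOSTICS, 0.7), (cfg.CENTRE_OUTPATIENT, 0.3)]
    ))
    b.categories = frozenset({CATEGORY_DIAGNOSIS})
    b.shares = {CATEGORY_DIAGNOSIS: total}
    return b


def _surgery_case(rng, config, pid, case, start, window_end):
    duration = int(rng.integers(5, 13))
    end = min(start + dt.timedelta(days=duration), window_end)
    if end < start:
        end = start
    unit = cfg.UNIT_THORACIC_SURGERY
    b = _CaseBuild(case, pid, CaseType.INPATIENT)
    b.claims.append(
        ServiceClaim(pid, case, start, CaseType.INPATIENT, unit, unit,
                     "thoracic surgery DRG lobectomy", "drg")
    )
    b.claims.append(
        ServiceClaim(pid, case, start + (end - start) / 2, CaseType.INPATIENT,
                     unit, "ward", "inpatient ward care", "stay")
    )
    b.claims.append(
        ServiceClaim(pid, case, end, CaseType.INPATIENT, unit, unit,
                     "discharge examination", "visit")
    )
    total = _draw_cost(rng, config.cost_model[Modality.SURGERY.value])

    complication = None
    if rng.random() < 0.25:
        complication = Complication(
            "post-operative pneumonia",
            end - dt.timedelta(days=1),
            min(end + dt.timedelta(days=9), window_end),
        )

    # readmission within 18 days reuses the same case number
    last = end
    if rng.random() < config.readmission_rate and end + dt.timedelta(days=20) <= window_end:
        re_start = end + dt.timedelta(days=int(rng.integers(3, 19)))
        re_end = min(re_start + dt.timedelta(days=int(rng.integers(2, 7))), window_end)
        b.claims.append(
            ServiceClaim(pid, case, re_start, CaseType.INPATIENT, unit, "ward",
                         "readmission same diagnostic category", "stay")
        )
        b.claims.append(
            ServiceClaim(pid, case, re_end, CaseType.INPATIENT, unit, unit,
                         "discharge examination", "visit")
        )
        total += _draw_cost(rng, CostModel(Decimal("8000"), 0.5))
        last = re_end
    _emit_costs(rng, b, last, _split_amount(
        total, [(cfg.CENTRE_OR, 0.55), (cfg.CENTRE_WARD, 0.45)]
    ))
    b.categories = frozenset({Modality.SURGERY.value})
    b.shares = {Modality.SURGERY.value: total}
    return b, TreatmentEpisode(Modality.SURGERY, start, end), complication


def _radiotherapy_case(rng, config, pid, case, start, window_end):
    n_fx = int(rng.integers(10, 31))
    span = min(int(round(n_fx * 7 / 5)), max((window_end - start).days, 1))
    end = start + dt.timedelta(days=span)
    unit = cfg.UNIT_RADIO_ONCOLOGY
    b = _CaseBuild(case, pid, CaseType.OUTPATIENT)
    b.claims.append(
        ServiceClaim(pid, case, start, CaseType.OUTPATIENT, unit, unit,
                     "radiotherapy planning CT and simulation", "planning")
    )
    day = 7
    while day < span:
        b.claims.append(
            ServiceClaim(pid, case, start + dt.timedelta(days=day),
                         CaseType.OUTPATIENT, unit, unit,
                         "radiotherapy fraction series", "fraction",
                         quantity=5.0)
        )
        day += 7
    b.claims.append(
        ServiceClaim(pid, case, end, CaseType.OUTPATIENT, unit, unit,
                     "radiotherapy fraction series, completion", "fraction")
    )
    total = _draw_cost(rng, config.cost_model[Modality.RADIOTHERAPY.value])
    parts = _split_amount(total, [(cfg.CENTRE_RADIO, 0.85), (cfg.CENTRE_OUTPATIENT, 0.15)])
    _emit_costs(rng, b, end, parts)
    b.categories = frozenset({Modality.RADIOTHERAPY.value})
    b.shares = {Modality.RADIOTHERAPY.value: total}
    b.radio_component = parts[0][1]
    return b, TreatmentEpisode(Modality.RADIOTHERAPY, start, end)


def _systemic_case(rng, config, pid, case, modality, start, window_end):
    model = config.cost_model[modality.value]
    prices = cfg.DRUG_PRICES[modality]
    drug = list(prices)[int(rng.integers(0, len(prices)))]
    unit_cost = prices[drug]

    total = _draw_cost(rng, model)
    floor = unit_cost + Decimal("500")
    if total < floor:
        total = chf(floor)
    target = total * Decimal(str(model.drug_fraction))
    qty = max(1, int(target / unit_cost))
    if unit_cost * qty > total - Decimal("200"):
        qty = max(1, int((total - Decimal("200")) / unit_cost))
    drug_cost = chf(unit_cost * qty)

    interval = 28 if modality is Modality.TARGETED_THERAPY else 21
    n_cycles = int(rng.integers(3, 7))
    max_fit = max((window_end - start).days // interval + 1, 1)
    n_cycles = max(1, min(n_cycles, max_fit, qty))
    per_cycle = qty // n_cycles
    remainder = qty - per_cycle * n_cycles

    unit = cfg.UNIT_ONCOLOGY_CLINIC
    b = _CaseBuild(case, pid, CaseType.OUTPATIENT)
    last = start
    for j in range(n_cycles):
        date = start + dt.timedelta(days=j * interval)
        q = per_cycle + (remainder if j == 0 else 0)
        b.claims.append(
            ServiceClaim(pid, case, date, CaseType.OUTPATIENT, unit, unit,
                         f"{drug} administration, cycle {j + 1}", "drug",
                         quantity=float(q))
        )
        b.claims.append(
            ServiceClaim(pid, case, date, CaseType.OUTPATIENT, unit, unit,
                         "oncology day-clinic visit", "visit")
        )
        last = date
    residual = total - drug_cost
    year, month = _billing(rng, last)
    b.costs.append(
        CostRecord(case, drug_cost, month, year, cfg.CENTRE_DRUGS)
    )
    _emit_costs(rng, b, last, [(cfg.CENTRE_OUTPATIENT, residual)])
    b.categories = frozenset({modality.value})
    b.shares = {modality.value: total}
    b.drug_components = {modality.value: drug_cost}
    return b, TreatmentEpisode(modality, start, last)


def _comorbidity_case(rng, config, pid, case, start, window_end):
    inpatient = rng.random() < 0.3
    case_type = CaseType.INPATIENT if inpatient else CaseType.OUTPATIENT
    unit = "internal medicine" if rng.random() < 0.6 else "cardiology"
    span = int(rng.integers(1, 6)) if inpatient else 0
    end = min(start + dt.timedelta(days=span), window_end)
    b = _CaseBuild(case, pid, case_type)
    b.claims.append(
        ServiceClaim(pid, case, start, case_type, unit, unit,
                     "comorbidity management consultation", "visit")
    )
    if end > start:
        b.claims.append(
            ServiceClaim(pid, case, end, case_type, unit, "ward",
                         "inpatient ward care", "stay")
        )
    total = _draw_cost(rng, config.cost_model[CATEGORY_OTHER])
    centre = cfg.CENTRE_WARD if inpatient else cfg.CENTRE_OUTPATIENT
    _emit_costs(rng, b, end, [(centre, total)])
    b.categories = frozenset({CATEGORY_OTHER})
    b.shares = {CATEGORY_OTHER: total}
    return b


def _death_case(rng, config, pid, case, death_date):
    start = death_date - dt.timedelta(days=7)
    unit = "intensive care"
    b = _CaseBuild(case, pid, CaseType.INPATIENT)
    b.claims.append(
        ServiceClaim(pid, case, start, CaseType.INPATIENT, unit, unit,
                     "emergency admission, respiratory failure", "stay")
    )
    b.claims.append(
        ServiceClaim(pid, case, death_date, CaseType.INPATIENT, unit, unit,
                     "inpatient end-of-life care", "stay")
    )
    total = _draw_cost(rng, config.cost_model[CATEGORY_DEATH])
    _emit_costs(rng, b, death_date, _split_amount(
        total, [(cfg.CENTRE_WARD, 0.6), ("intensive care", 0.4)]
    ))
    b.categories = frozenset({CATEGORY_DEATH})
    b.shares = {CATEGORY_DEATH: total}
    return b


_VISITS = [(Timepoint.BL, 0), (Timepoint.M3, 91), (Timepoint.M6, 182), (Timepoint.M12, 365)]


def _generate_proms(rng, config, d0, stage, episodes, cutoff_day):
    pm = config.prom_model
    score = float(np.clip(rng.normal(pm.baseline_mean, pm.baseline_sd), 0, 100))
    proms: list[PromAssessment] = []
    prev_day = -1
    for timepoint, day in _VISITS:
        if day > cutoff_day:
            break  # monotone dropout after death / deactivation
        if timepoint is not Timepoint.BL:
            drift = pm.stage_drift.get(stage, 0.0)
            for ep in episodes:
                ep_day = (ep.start_date - d0).days
                if prev_day < ep_day <= day:
                    drift += pm.modality_drift.get(ep.modality, 0.0)
            score = float(np.clip(score + drift + rng.normal(0, pm.visit_sd), 0, 100))
        missing_p = pm.baseline_missing_rate if timepoint is Timepoint.BL else pm.missing_rate
        missing = rng.random() < missing_p
        jitter = int(rng.integers(0, 6))
        proms.append(
            PromAssessment(
                timepoint=timepoint,
                assessment_date=d0 + dt.timedelta(days=day + jitter),
                qlq_c30_summary_score=None if missing else round(score, 1),
            )
        )
        prev_day = day
    return proms


# ---------------------------------------------------------------------------
# inconsistency injection


def inject_inconsistencies(
    service: list[ServiceClaim],
    costs: list[CostRecord],
    ledger: GroundTruthLedger,
    rates: InconsistencyRates,
    seed: int,
) -> tuple[list[ServiceClaim], list[CostRecord]]:
    """Corrupt consistent datasets the way real hospital exports are.

    Three corruption types, each decided per case with its own uniform
    draw (so different rates under one seed are nested): blanking drug
    names from the service text, deleting claims and cost lines of
    externally purchased targeted drugs, and appending orphan cost
    lines under case numbers unknown to the service dataset.  The
    ledger is annotated with every corruption applied; shares of
    external-pharmacy cases are reduced by the removed drug cost so the
    ledger stays consistent with the emitted files.
    """
    rng = np.random.default_rng(seed)
    tokens = sorted(cfg.all_drug_unit_costs())
    targeted_tokens = sorted(cfg.DRUG_PRICES[Modality.TARGETED_THERAPY])

    blank_cases: set[str] = set()
    external_cases: set[str] = set()
    orphan_sources: list[str] = []
    for case in sorted(ledger.entries):
        entry = ledger.entries[case]
        u_blank, u_external, u_orphan = rng.random(3)
        has_drugs = bool(entry.drug_components)
        targeted = Modality.TARGETED_THERAPY.value in entry.categories
        if has_drugs and u_blank < rates.blank_drug:
            blank_cases.add(case)
        if targeted and u_external < rates.external_pharmacy:
            external_cases.add(case)
        if u_orphan < rates.orphan_cost:
            orphan_sources.append(case)

    new_service: list[ServiceClaim] = []
    for claim in service:
        if claim.case_number in external_cases and any(
            t in claim.service_text.lower() for t in targeted_tokens
        ):
            continue  # drug purchased at an external pharmacy: never claimed
        if claim.case_number in blank_cases:
            text = claim.service_text
            lower = text.lower()
            for t in tokens:
                if t in lower:
                    idx = lower.index(t)
                    text = text[:idx] + "medication (unspecified)" + text[idx + len(t):]
                    lower = text.lower()
            claim = replace(claim, service_text=text)
        new_service.append(claim)

    new_costs: list[CostRecord] = []
    for cost in costs:
        if cost.case_number in external_cases and cost.cost_centre_type == cfg.CENTRE_DRUGS:
            continue  # the hospital never incurred the drug cost
        new_costs.append(cost)

    for case in blank_cases:
        e = ledger.entries[case]
        e.corruptions = e.corruptions + ("blank_drug",)
    for case in external_cases:
        e = ledger.entries[case]
        removed = e.drug_components.pop(Modality.TARGETED_THERAPY.value, Decimal("0.00"))
        e.shares[Modality.TARGETED_THERAPY.value] = (
            e.shares.get(Modality.TARGETED_THERAPY.value, Decimal("0.00")) - removed
        )
        e.corruptions = e.corruptions + ("external_pharmacy",)

    for j, source in enumerate(orphan_sources):
        amount = chf(round(rng.lognormal(math.log(2000), 1.0), 2))
        month = int(rng.integers(1, 13))
        year = 2021 + int(rng.integers(0, 3))
        orphan_case = f"ORPH-{j + 1:04d}"
        new_costs.append(
            CostRecord(orphan_case, amount, month, year, cfg.CENTRE_WARD)
        )
        ledger.orphan_cases.append(orphan_case)

    return new_service, new_costs


def write_datasets(
    clinical, service, costs, ledger, directory: str | Path
) -> None:
    """Write clinical.csv (+companions), service.csv, costs.csv, ledger.csv."""
    from .io import write_clinical, write_costs, write_service

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_clinical(clinical, directory)
    write_service(service, directory / "service.csv")
    write_costs(costs, directory / "costs.csv")
    ledger.write(directory / "ledger.csv")
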