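import datetime as dt
from decimal import Decimal

import numpy as np
import pytest
from conftest import D0, make_claim, make_cost, make_grouped, make_patient

from vbhc.assign import (
    AssignmentRuleSet,
    assign_categories,
    match_case,
    split_case_costs,
    validate_allocation,
)
from vbhc.config import default_rules
from vbhc.merge import merge_step1
from vbhc.records import (
    CaseType,
    Modality,
    TreatmentEpisode,
    chf,
)
from vbhc.simulate import GeneratorConfig, InconsistencyRates, generate


def days(n):
    return D0 + dt.timedelta(days=n)


class TestCategoryAssignment:
    def test_drug_match_assigns_systemic_therapy(self, rules):
        episode = TreatmentEpisode(Modality.IMMUNOTHERAPY, days(10), days(73))
        case = make_grouped(
            claims=[make_claim(text="pembrolizumab administration, cycle 1",
                               date=days(10))],
            first=days(10), last=days(73), treatments=[episode],
        )
        (assignment,) = assign_categories([case], rules)
        assert assignment.categories == {"immunotherapy"}
        assert assignment.shares[0].evidence == ("drug:pembrolizumab",)

    def test_inpatient_surgery_unit_with_overlap(self, rules):
        episode = TreatmentEpisode(Modality.SURGERY, days(10), days(20))
        case = make_grouped(
            case_type=CaseType.INPATIENT,
            org_units={"thoracic surgery", "ward"},
            claims=[make_claim(case_type=CaseType.INPATIENT, date=days(10))],
            first=days(10), last=days(20), treatments=[episode],
        )
        (assignment,) = assign_categories([case], rules)
        assert assignment.categories == {"surgery"}

    def test_surgery_unit_without_episode_overlap_not_assigned(self, rules):
        episode = TreatmentEpisode(Modality.SURGERY, days(100), days(110))
        case = make_grouped(
            case_type=CaseType.INPATIENT,
            org_units={"thoracic surgery"},
            first=days(10), last=days(20), treatments=[episode],
        )
        (assignment,) = assign_categories([case], rules)
        assert "surgery" not in assignment.categories

    def test_unmatched_case_diagnosis_before_first_treatment_else_other(self, rules):
        episode = TreatmentEpisode(Modality.CHEMOTHERAPY, days(30), days(90))
        before = make_grouped(case="K1", first=days(5), last=days(6),
                              treatments=[episode])
        after = make_grouped(case="K2", first=days(120), last=days(121),
                             treatments=[episode])
        by_case = {
            a.case_number: a for a in assign_categories([before, after], rules)
        }
        assert by_case["K1"].categories == {"diagnosis"}
        assert by_case["K2"].categories == {"other"}

    def test_death_in_hospital_assigned_to_last_case_only(self, rules):
        early = make_grouped(case="K1", first=days(5), death_in_hospital=True)
        last = make_grouped(case="K2", first=days(200), death_in_hospital=True)
        by_case = {a.case_number: a for a in assign_categories([early, last], rules)}
        assert by_case["K2"].categories == {"death_in_hospital"}
        assert "death_in_hospital" not in by_case["K1"].categories

    def test_radiotherapy_never_coassigned_with_inpatient_surgery(self, rules):
        """On clean generator output the inpatient surgical case never
        carries a radiotherapy co-assignment."""
        clinical, service, costs, _ = generate(GeneratorConfig(n_patients=80, seed=21))
        assignments = assign_categories(merge_step1(clinical, service, costs), rules)
        for a in assignments:
            if a.case_type == CaseType.INPATIENT and "surgery" in a.categories:
                assert "radiotherapy" not in a.categories

    def test_empty_rule_set_rejected(self):
        with pytest.raises(ValueError):
            AssignmentRuleSet(rules={})


class TestCostSplitting:
    def test_two_categories_no_attribution_splits_evenly(self, rules):
        case = make_grouped(total="100.00")
        a = split_case_costs(
            case, {"chemotherapy": (), "radiotherapy": ()}, rules
        )
        assert [str(s.cost_share) for s in a.shares] == ["50.00", "50.00"]

    def test_three_tier_split_matches_stated_rule(self, rules):
        """Total 1000, drug-attributable 300, radiotherapy-attributable 200:
        chemo gets 300+250, radiotherapy 200+250."""
        claims = [make_claim(text="paclitaxel administration", date=D0,
                             quantity=1.0)]
        cost_lines = [make_cost(amount="200.00", centre="radio-oncology"),
                      make_cost(amount="800.00", centre="outpatient clinic")]
        case = make_grouped(total="1000.00", claims=claims, cost_lines=cost_lines)
        test_rules = AssignmentRuleSet(
            rules=rules.rules,
            drug_unit_costs={"paclitaxel": Decimal("300.00")},
            radio_cost_centre_patterns=("radio",),
        )
        matches = match_case(case, test_rules)
        a = split_case_costs(
            case, {"chemotherapy": (), "radiotherapy": ()}, test_rules, matches
        )
        assert a.share_of("chemotherapy") == Decimal("550.00")
        assert a.share_of("radiotherapy") == Decimal("450.00")

    def test_single_category_receives_everything(self, rules):
        case = make_grouped(total="777.77",
                            cost_lines=[make_cost(amount="777.77", centre="radio")])
        a = split_case_costs(case, {"radiotherapy": ()}, rules)
        assert a.share_of("radiotherapy") == Decimal("777.77")

    def test_odd_cent_goes_to_first_category_deterministically(self, rules):
        case = make_grouped(total="100.01")
        a = split_case_costs(case, {"chemotherapy": (), "surgery": ()}, rules)
        assert a.share_of("chemotherapy") == Decimal("50.01")
        assert a.share_of("surgery") == Decimal("50.00")

    def test_attribution_exceeding_total_is_hard_error(self, rules):
        claims = [make_claim(text="pembrolizumab administration", quantity=10.0)]
        case = make_grouped(total="100.00", claims=claims)
        matches = match_case(case, rules)
        with pytest.raises(ValueError, match="exceed"):
            split_case_costs(
                case, {"immunotherapy": (), "other": ()}, rules, matches
            )

    def test_random_multi_category_cases_conserve_totals_exactly(self, rules):
        """1000 random multi-treatment cases: shares always sum to the total."""
        rng = np.random.default_rng(123)
        categories_pool = [
            "chemotherapy", "immunotherapy", "targeted_therapy",
            "surgery", "radiotherapy", "other", "death_in_hospital",
        ]
        drug_of = {
            "chemotherapy": "carboplatin",
            "immunotherapy": "nivolumab",
            "targeted_therapy": "osimertinib",
        }
        for i in range(1000):
            k = int(rng.integers(2, 5))
            names = list(rng.choice(categories_pool, size=k, replace=False))
            total = chf(round(float(rng.lognormal(np.log(20000), 1.0)), 2))
            claims, cost_lines = [], []
            for name in names:
                if name in drug_of:
                    qty = int(rng.integers(1, 4))
                    unit = rules.drug_unit_costs[drug_of[name]]
                    if unit * qty < total * Decimal("0.3"):
                        claims.append(make_claim(
                            text=f"{drug_of[name]} administration",
                            quantity=float(qty),
                        ))
            if "radiotherapy" in names:
                radio_amount = chf(total * Decimal("0.2"))
                cost_lines.append(make_cost(amount=str(radio_amount),
                                            centre="radio-oncology"))
            case = make_grouped(case=f"K{i}", total=str(total), claims=claims,
                                cost_lines=cost_lines)
            matches = match_case(case, rules)
            try:
                a = split_case_costs(case, {n: () for n in names}, rules, matches)
            except ValueError:
                continue  # attribution exceeded the drawn total: rejected loudly
            assert sum(s.cost_share for s in a.shares) == total
            assert all(s.cost_share >= 0 for s in a.shares)


class TestAllocationValidation:
    def test_clean_cohort_has_full_allocation_and_exact_totals(self, rules,
                                                               small_cohort):
        clinical, service, costs, ledger = small_cohort
        assignments = assign_categories(merge_step1(clinical, service, costs), rules)
        report = validate_allocation(assignments, clinical, ledger)
        for modality, alloc in report.by_modality.items():
            if alloc.n_patients_with_episode:
                assert alloc.allocation_rate == 100.0, modality
        assert report.category_recovery_rate == 100.0
        assert report.max_patient_total_error == Decimal("0.00")
        assert report.n_patient_totals_exact == report.n_patient_totals

    def test_every_surgery_maps_to_exactly_one_case(self, rules, small_cohort):
        clinical, service, costs, _ = small_cohort
        assignments = assign_categories(merge_step1(clinical, service, costs), rules)
        for record in clinical:
            n_surgeries = sum(
                ep.modality is Modality.SURGERY for ep in record.treatments
            )
            n_cases = sum(
                "surgery" in a.categories
                for a in assignments if a.patient_id == record.patient_id
            )
            if n_surgeries:
                assert n_cases == n_surgeries == 1

    def test_blanking_all_drug_text_zeroes_targeted_allocation(self, rules):
        from vbhc.records import Stage

        policy = {stage: [((Modality.TARGETED_THERAPY,), 1.0)]
                  for stage in (Stage.I, Stage.II, Stage.III, Stage.IV)}
        config = GeneratorConfig(
            n_patients=20, seed=6, treatment_policy=policy,
            death_rates={s: 0.0 for s in Stage},
            inconsistency_rates=InconsistencyRates(blank_drug=1.0),
        )
        clinical, service, costs, ledger = generate(config)
        assignments = assign_categories(merge_step1(clinical, service, costs), rules)
        report = validate_allocation(assignments, clinical, ledger)
        assert report.by_modality["targeted_therapy"].allocation_rate == 0.0
        assert report.by_modality["surgery"].n_patients_with_episode == 0

    def test_empty_cohort_yields_empty_report(self, rules):
        report = validate_allocation([], [])
        assert report.n_cases == 0
        assert all(
            a.n_patients_with_episode == 0 for a in report.by_modality.values()
        )
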