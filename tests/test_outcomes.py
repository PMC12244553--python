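import datetime as dt
from decimal import Decimal

import numpy as np
import pandas as pd
import pytest
from conftest import D0, make_patient
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vbhc.assign import assign_categories, patient_category_totals
from vbhc.merge import merge_step1
from vbhc.outcomes import (
    IDENTITY_MAPPING,
    UtilityMapping,
    build_patient_outcomes,
    derive_utilities,
    partial_correlation,
    spearman,
    summarize_costs,
)
from vbhc.records import (
    Modality,
    PromAssessment,
    Timepoint,
    TreatmentEpisode,
)

# ---------------------------------------------------------------------------
# independent oracles


def rank_then_pearson(x, y):
    """Brute-force Spearman: average ranks, then Pearson."""
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def precision_matrix_partial(x, y, Z):
    """Partial correlation from the inverse covariance of (x, y, Z)."""
    M = np.column_stack([x, y, Z])
    P = np.linalg.inv(np.cov(M, rowvar=False))
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


# ---------------------------------------------------------------------------
# utilities


class TestUtilityMapping:
    def test_identity_mapping_maps_100_to_1(self):
        assert IDENTITY_MAPPING(100.0) == pytest.approx(1.0)
        assert IDENTITY_MAPPING(0.0) == 0.0

    def test_affine_mapping_hand_value(self):
        mapping = UtilityMapping(name="affine", intercept=0.2, slope=0.006)
        assert mapping(50.0) == pytest.approx(0.5)

    def test_missing_score_stays_missing(self):
        assert IDENTITY_MAPPING(None) is None

    def test_non_monotone_mapping_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            UtilityMapping(name="bad", slope=-0.01)
        with pytest.raises(ValueError, match="monotone"):
            UtilityMapping(name="bad", nodes=((0.0, 0.5), (100.0, 0.2)))

    def test_derive_utilities_row_per_assessment(self):
        rec = make_patient("P1", prom_assessments=[
            PromAssessment(Timepoint.BL, D0, 80.0),
            PromAssessment(Timepoint.M3, D0 + dt.timedelta(days=91), None),
        ])
        frame = derive_utilities([rec])
        assert len(frame) == 2
        assert frame.loc[0, "utility"] == pytest.approx(0.8)
        assert np.isnan(frame.loc[1, "utility"])


class TestPatientOutcomes:
    def test_change_uses_last_available_visit_within_fu(self):
        rec = make_patient("P1", prom_assessments=[
            PromAssessment(Timepoint.BL, D0, 80.0),
            PromAssessment(Timepoint.M3, D0 + dt.timedelta(days=91), 60.0),
            PromAssessment(Timepoint.M6, D0 + dt.timedelta(days=182), None),
            PromAssessment(Timepoint.M12, D0 + dt.timedelta(days=400), 90.0),
        ])
        (row,) = build_patient_outcomes([rec], []).to_dict("records")
        # M6 is missing, M12 is outside the 365-day window: M3 is last
        assert row["utility_change"] == pytest.approx(0.6 - 0.8)

    def test_missing_baseline_gives_undefined_change(self):
        rec = make_patient("P1", prom_assessments=[
            PromAssessment(Timepoint.BL, D0, None),
            PromAssessment(Timepoint.M3, D0 + dt.timedelta(days=91), 60.0),
        ])
        (row,) = build_patient_outcomes([rec], []).to_dict("records")
        assert np.isnan(row["utility_change"])

    def test_first_treatment_modality_recorded(self):
        rec = make_patient("P1", treatments=[
            TreatmentEpisode(Modality.CHEMOTHERAPY, D0 + dt.timedelta(days=40),
                             D0 + dt.timedelta(days=100)),
            TreatmentEpisode(Modality.SURGERY, D0 + dt.timedelta(days=10),
                             D0 + dt.timedelta(days=20)),
        ])
        (row,) = build_patient_outcomes([rec], []).to_dict("records")
        assert row["first_treatment_modality"] == "surgery"


# ---------------------------------------------------------------------------
# cost summaries


class TestCostSummaries:
    def test_single_patient_single_case(self, rules, small_cohort):
        from conftest import make_grouped

        from vbhc.assign import split_case_costs

        case = make_grouped(total="100.00")
        a = split_case_costs(case, {"surgery": ()}, rules)
        (summary,) = [s for s in summarize_costs([a]) if s.group == "surgery"]
        assert summary.n_patients == 1
        assert summary.median == summary.mean == 100.0
        assert np.isnan(summary.sd)

    def test_three_patient_hand_statistics(self, rules):
        from conftest import make_grouped

        from vbhc.assign import split_case_costs

        assignments = [
            split_case_costs(
                make_grouped(case=f"K{i}", pid=f"P{i}", total=str(t)),
                {"surgery": ()}, rules,
            )
            for i, t in enumerate(("10.00", "20.00", "90.00"))
        ]
        (summary,) = [s for s in summarize_costs(assignments) if s.group == "surgery"]
        assert summary.median == 20.0
        assert summary.mean == 40.0
        assert summary.q25 == 15.0 and summary.q75 == 55.0  # linear interpolation
        assert summary.min == 10.0 and summary.max == 90.0

    def test_case_type_split_sums_to_overall_total(self, rules, small_cohort):
        clinical, service, costs, _ = small_cohort
        assignments = assign_categories(merge_step1(clinical, service, costs), rules)
        overall = sum(float(a.total_cost) for a in assignments)
        split = {
            s.group: s.mean * s.n_patients
            for s in summarize_costs(assignments, group_by="case_type")
        }
        assert sum(split.values()) == pytest.approx(overall, abs=0.05)

    def test_category_partition_conserves_grand_totals_exactly(self, rules,
                                                               small_cohort):
        """Summed over the category partition, each patient's shares equal
        their full first-year cost, cent for cent."""
        clinical, service, costs, _ = small_cohort
        assignments = assign_categories(merge_step1(clinical, service, costs), rules)
        per_patient = {}
        for (pid, _cat), amount in patient_category_totals(assignments).items():
            per_patient[pid] = per_patient.get(pid, Decimal("0.00")) + amount
        grand = {}
        for a in assignments:
            grand[a.patient_id] = grand.get(a.patient_id, Decimal("0.00")) + a.total_cost
        assert per_patient == grand


# ---------------------------------------------------------------------------
# correlations


class TestSpearman:
    def test_perfectly_increasing_pairs(self):
        result = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert result.coefficient == pytest.approx(1.0)

    def test_reversed_pair_is_minus_one(self):
        assert spearman([1, 2, 5], [2, 1, 0]).coefficient == pytest.approx(-1.0)

    def test_tied_fixture_matches_rank_then_pearson_oracle(self):
        x = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]  # one tie in x
        y = [10.0, 8.0, 12.0, 11.0, 9.0, 30.0]
        result = spearman(x, y)
        assert result.coefficient == pytest.approx(rank_then_pearson(x, y), abs=1e-12)
        assert result.n == 6

    def test_fewer_than_three_pairs_not_estimable(self):
        result = spearman([1, 2], [2, 1])
        assert not result.estimable and result.coefficient is None

    def test_missing_pairs_dropped(self):
        result = spearman([1, 2, np.nan, 4], [1, np.nan, 3, 4])
        assert result.n == 2
        assert not result.estimable

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=3, max_size=25,
        ),
        a=st.integers(1, 5),
        b=st.integers(1, 5),
    )
    def test_invariant_under_strictly_increasing_transforms(self, data, a, b):
        x = np.array([p[0] for p in data], dtype=float)
        y = np.array([p[1] for p in data], dtype=float)
        base = spearman(x, y)
        transformed = spearman(np.exp(x / 50.0) * a, y**3 * b + y)
        if base.estimable and not np.isnan(base.coefficient):
            assert transformed.coefficient == pytest.approx(
                base.coefficient, abs=1e-9
            )


class TestPartialCorrelation:
    def test_orthogonal_covariate_equals_plain_pearson(self):
        # covariate constructed orthogonal to both focal variables
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        z = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        A = np.column_stack([np.ones_like(x), x, y])
        z = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]  # z ⟂ span{1, x, y}
        result = partial_correlation(x, y, z[:, None])
        plain = float(np.corrcoef(x, y)[0, 1])
        assert result.coefficient == pytest.approx(plain, abs=1e-10)

    def test_fully_mediated_pair_has_near_zero_partial(self):
        rng = np.random.default_rng(7)
        n = 10000
        z = rng.normal(size=n)
        x = z + rng.normal(scale=1.0, size=n)
        y = z + rng.normal(scale=1.0, size=n)
        marginal = float(np.corrcoef(x, y)[0, 1])
        result = partial_correlation(x, y, z[:, None])
        assert marginal > 0.4
        assert abs(result.coefficient) < 0.03

    def test_eight_row_fixture_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        Z = rng.normal(size=(8, 2))
        result = partial_correlation(x, y, Z)
        assert result.coefficient == pytest.approx(
            precision_matrix_partial(x, y, Z), abs=1e-10
        )

    def test_residualisation_equals_precision_oracle_on_random_fixtures(self):
        """Frisch-Waugh-Lovell: the two definitions agree to 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(1, 4))
            Z = rng.normal(size=(n, k))
            beta = rng.normal(size=k)
            x = Z @ beta + rng.normal(size=n)
            y = Z @ rng.normal(size=k) + 0.5 * x + rng.normal(size=n)
            result = partial_correlation(x, y, Z)
            assert result.coefficient == pytest.approx(
                precision_matrix_partial(x, y, Z), abs=1e-10
            )

    def test_collinear_covariate_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        z = rng.normal(size=12)
        Z = np.column_stack([z, 2 * z])
        result = partial_correlation(x, y, Z, covariate_names=["z", "z2"])
        assert result.dropped_covariates == ("z2",)
        assert result.covariates == ("z",)

    def test_insufficient_n_flagged_not_estimable(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        Z = np.eye(4)[:, :2]
        result = partial_correlation(x, y, Z)
        assert not result.estimable and result.coefficient is None
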