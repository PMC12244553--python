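"""Utilities, cost summaries and cost-outcome correlation analyses.

Health-state utilities are derived from the EORTC QLQ-C30 summary score
(0-100, higher is better) through a pluggable, monotone mapping loaded
from configuration; published score-to-utility algorithms can be
transcribed into such a coefficient set.  Missing scores stay missing —
baseline scores are never imputed, and patients without a baseline are
excluded from utility analyses downstream, not here.

Cost summaries follow the convention of summarising per patient first:
the shares assigned to a group (treatment category, stage, inpatient /
outpatient) are summed per patient and the distributional statistics
are computed over those patient-level totals.  Quantiles use linear
interpolation between order statistics; the standard deviation of a
single observation is reported as missing.

The cost-utility association is quantified by rank-based Spearman
correlation and by the partial correlation of first-year cost and
utility change given covariates (baseline utility and the type of first
treatment).  The partial correlation is computed by residualising both
focal variables on the covariates and correlating the residuals, which
is numerically identical to the precision-matrix definition and to the
saturated path-model (SEM) estimate of the same quantity.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .assign import CaseAssignment, patient_category_totals
from .records import (
    SYSTEMIC_MODALITIES,
    PatientClinicalRecord,
    Timepoint,
)

log = logging.getLogger(__name__)

TIMEPOINT_ORDER = [Timepoint.BL, Timepoint.M3, Timepoint.M6, Timepoint.M12]


# ---------------------------------------------------------------------------
# utility mapping


@dataclass(frozen=True)
class UtilityMapping:
    """Monotone map from QLQ-C30 summary score (0-100) to a utility value.

    Affine form ``u = intercept + slope * score`` with ``slope >= 0``;
    an optional piecewise-linear node list overrides the affine form.
    """

    name: str
    intercept: float = 0.0
    slope: float = 0.01
    nodes: tuple[tuple[float, float], ...] = ()  # (score, utility), sorted

    def __post_init__(self):
        if self.nodes:
            xs = [x for x, _ in self.nodes]
            ys = [y for _, y in self.nodes]
            if sorted(xs) != xs or any(b < a for a, b in zip(ys, ys[1:])):
                raise ValueError(f"utility mapping {self.name!r} is not monotone")
        elif self.slope < 0:
            raise ValueError(f"utility mapping {self.name!r} is not monotone")

    def __call__(self, score: Optional[float]) -> Optional[float]:
        if score is None or (isinstance(score, float) and np.isnan(score)):
            return None
        if self.nodes:
            xs = np.array([x for x, _ in self.nodes])
            ys = np.array([y for _, y in self.nodes])
            return float(np.interp(score, xs, ys))
        return self.intercept + self.slope * score

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UtilityMapping":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw.get("name", "unnamed"),
            intercept=float(raw.get("intercept", 0.0)),
            slope=float(raw.get("slope", 0.01)),
            nodes=tuple((float(x), float(y)) for x, y in raw.get("nodes", [])),
        )


#: score/100 — a transparent placeholder used when no published
#: coefficient set has been configured.
IDENTITY_MAPPING = UtilityMapping(name="identity", intercept=0.0, slope=0.01)


def derive_utilities(
    clinical: Sequence[PatientClinicalRecord],
    mapping: UtilityMapping = IDENTITY_MAPPING,
) -> pd.DataFrame:
    """One row per PROM assessment with the mapped utility (NaN if missing)."""
    rows = []
    for rec in clinical:
        for a in rec.prom_assessments:
            utility = mapping(a.qlq_c30_summary_score)
            rows.append({
                "patient_id": rec.patient_id,
                "timepoint": a.timepoint.value,
                "assessment_date": a.assessment_date,
                "qlq_c30_summary_score": a.qlq_c30_summary_score,
                "utility": np.nan if utility is None else utility,
            })
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint", "assessment_date",
            "qlq_c30_summary_score", "utility",
        ],
    )


# ---------------------------------------------------------------------------
# patient outcomes


@dataclass
class PatientOutcome:
    patient_id: str
    baseline_utility: Optional[float]
    last_utility: Optional[float]
    utility_change: Optional[float]
    first_treatment_modality: Optional[str]
    total_first_year_cost: float
    stage: str
    histology: str


def build_patient_outcomes(
    clinical: Sequence[PatientClinicalRecord],
    assignments: Sequence[CaseAssignment],
    mapping: UtilityMapping = IDENTITY_MAPPING,
    fu_days: int = 365,
) -> pd.DataFrame:
    """Per-patient analysis table: utilities, change, first treatment, cost.

    The utility change uses the last available (non-missing) assessment
    within the follow-up window, not a fixed visit; it is only defined
    when a baseline utility exists.
    """
    totals = patient_category_totals(list(assignments))
    cost_per_patient: dict[str, float] = {}
    for (pid, _category), amount in totals.items():
        cost_per_patient[pid] = cost_per_patient.get(pid, 0.0) + float(amount)

    rows = []
    for rec in clinical:
        cutoff = rec.diagnosis_date + dt.timedelta(days=fu_days)
        baseline = None
        last: tuple[int, float] | None = None
        for a in rec.prom_assessments:
            u = mapping(a.qlq_c30_summary_score)
            if u is None:
                continue
            order = TIMEPOINT_ORDER.index(a.timepoint)
            if a.timepoint is Timepoint.BL:
                baseline = u
            elif a.assessment_date <= cutoff and (last is None or order > last[0]):
                last = (order, u)
        change = None
        if baseline is not None and last is not None:
            change = last[1] - baseline
        first_ep = min(rec.treatments, key=lambda ep: ep.start_date, default=None)
        rows.append({
            "patient_id": rec.patient_id,
            "baseline_utility": np.nan if baseline is None else baseline,
            "last_utility": np.nan if last is None else last[1],
            "utility_change": np.nan if change is None else change,
            "first_treatment_modality": first_ep.modality.value if first_ep else None,
            "total_first_year_cost": cost_per_patient.get(rec.patient_id, 0.0),
            "stage": rec.stage.value,
            "histology": rec.histology.value,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cost summaries


@dataclass(frozen=True)
class CostSummary:
    group: str
    n_patients: int
    median: float
    q25: float
    q75: float
    mean: float
    sd: float  # NaN when n == 1
    min: float
    max: float


SYSTEMIC_GROUP = "systemic"


def summarize_costs(
    assignments: Sequence[CaseAssignment],
    clinical: Sequence[PatientClinicalRecord] | None = None,
    group_by: str = "category",
) -> list[CostSummary]:
    """Distributional cost statistics over patient-level group totals.

    ``group_by`` is one of:

    - ``"category"``: one group per assigned category, plus a pooled
      "systemic" group (chemo/immuno/targeted combined) and a "total"
      group over each patient's full first-year cost;
    - ``"stage"``: each patient's total cost, grouped by stage at
      diagnosis (requires ``clinical``);
    - ``"case_type"``: each patient's cost split into inpatient and
      outpatient shares.

    Empty groups are omitted (with a log note).
    """
    assignments = list(assignments)
    groups: dict[str, dict[str, float]] = {}

    def accumulate(group: str, pid: str, amount: float) -> None:
        groups.setdefault(group, {})
        groups[group][pid] = groups[group].get(pid, 0.0) + amount

    if group_by == "category":
        for a in assignments:
            for s in a.shares:
                amount = float(s.cost_share)
                accumulate(s.category, a.patient_id, amount)
                if s.category in {m.value for m in SYSTEMIC_MODALITIES}:
                    accumulate(SYSTEMIC_GROUP, a.patient_id, amount)
                accumulate("total", a.patient_id, amount)
    elif group_by == "stage":
        if clinical is None:
            raise ValueError("group_by='stage' requires the clinical dataset")
        stage = {r.patient_id: r.stage.value for r in clinical}
        for a in assignments:
            accumulate(stage.get(a.patient_id, "unknown"), a.patient_id,
                       float(a.total_cost))
    elif group_by == "case_type":
        for a in assignments:
            accumulate(a.case_type.value, a.patient_id, float(a.total_cost))
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    summaries = []
    for group in sorted(groups):
        totals = np.array(sorted(groups[group].values()), dtype=float)
        if totals.size == 0:
            log.info("cost group %r is empty, omitted", group)
            continue
        q25, med, q75 = np.quantile(totals, [0.25, 0.5, 0.75])  # linear interp
        summaries.append(
            CostSummary(
                group=group,
                n_patients=totals.size,
                median=float(med),
                q25=float(q25),
                q75=float(q75),
                mean=float(totals.mean()),
                sd=float(totals.std(ddof=1)) if totals.size > 1 else float("nan"),
                min=float(totals.min()),
                max=float(totals.max()),
            )
        )
    return summaries


def summaries_to_frame(summaries: list[CostSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: Optional[float]
    n: int
    estimable: bool
    covariates: tuple[str, ...] = ()
    dropped_covariates: tuple[str, ...] = ()


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing member are dropped; fewer than 3 complete
    pairs is flagged as not estimable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        return CorrelationResult(None, n, False)
    rho = stats.spearmanr(x, y).statistic
    return CorrelationResult(float(rho), n, True)


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | np.ndarray,
    covariate_names: Sequence[str] | None = None,
) -> CorrelationResult:
    """Partial correlation of ``x`` and ``y`` given ``covariates``.

    Both focal variables are residualised on the covariates (with an
    intercept) by least squares and the residuals are Pearson-
    correlated; this equals the negative-normalised off-diagonal of the
    precision matrix of ``(x, y, covariates)``.  Collinear covariate
    columns are dropped with a warning.  Requires ``n > k + 2`` for
    ``k`` retained covariates.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        Z = covariates.to_numpy(dtype=float)
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        names = list(covariate_names or [f"z{i}" for i in range(Z.shape[1])])
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    x, y, Z = x[mask], y[mask], Z[mask]
    n = int(x.size)

    # drop collinear columns (including constants, which duplicate the intercept)
    kept: list[int] = []
    dropped: list[str] = []
    base = np.ones((n, 1))
    for j in range(Z.shape[1]):
        candidate = np.column_stack([base, Z[:, kept + [j]]]) if n else None
        if n and np.linalg.matrix_rank(candidate) == len(kept) + 2:
            kept.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        log.warning("partial_correlation: dropped collinear covariates %s", dropped)
    Zk = Z[:, kept]
    kept_names = tuple(names[j] for j in kept)

    if n <= Zk.shape[1] + 2:
        return CorrelationResult(None, n, False, kept_names, tuple(dropped))

    design = np.column_stack([np.ones(n), Zk])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return CorrelationResult(None, n, False, kept_names, tuple(dropped))
    return CorrelationResult(
        float((rx @ ry) / denom), n, True, kept_names, tuple(dropped)
    )


def first_treatment_design(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Covariate matrix: baseline utility + one-hot first treatment.

    The most frequent first-treatment modality is the reference
    category (its indicator column is omitted).
    """
    df = outcomes.copy()
    cov = pd.DataFrame({"baseline_utility": df["baseline_utility"]}, index=df.index)
    modalities = df["first_treatment_modality"].fillna("none")
    counts = modalities.value_counts()
    if not counts.empty:
        reference = counts.index[0]
        for m in sorted(counts.index):
            if m == reference:
                continue
            cov[f"first_tx_{m}"] = (modalities == m).astype(float)
    return cov


def correlations_by_stratum(
    outcomes: pd.DataFrame,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman and adjusted partial correlations per histology x stage.

    Patients without baseline or follow-up utility are excluded.  The
    partial correlation adjusts for baseline utility and the type of
    first treatment.
    """
    complete = outcomes.dropna(subset=["utility_change", "baseline_utility"])
    rows = []
    for (histology, stage), sub in complete.groupby(["histology", "stage"]):
        if len(sub) < min_n:
            continue
        sp = spearman(sub["total_first_year_cost"], sub["utility_change"])
        pc = partial_correlation(
            sub["total_first_year_cost"].to_numpy(),
            sub["utility_change"].to_numpy(),
            first_treatment_design(sub),
        )
        rows.append({
            "histology": histology,
            "stage": stage,
            "n": sp.n,
            "spearman": sp.coefficient if sp.estimable else np.nan,
            "partial": pc.coefficient if pc.estimable else np.nan,
            "partial_covariates": ",".join(pc.covariates),
        })
    return pd.DataFrame(
        rows,
        columns=["histology", "stage", "n", "spearman", "partial", "partial_covariates"],
    )
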