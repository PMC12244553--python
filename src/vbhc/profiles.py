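"""Per-patient timeline profiles: monthly cost spreading and rendering.

Case-level costs have no service-level dates, so for presentation the
total of each case is spread uniformly over the days between the case
opening date and the case closing date (a single-day case counts as one
day) and then summed into calendar months anchored at the start of the
patient's follow-up.  The spreading conserves each case's total
exactly: month amounts are rounded to the cent and the final month of
the case absorbs the rounding residue.

The rendered profile shows monthly costs as a grey area against the
left axis, the QLQ-C30 summary score and derived utility as lines
against the right axis, and horizontal category bands (diagnosis, each
treatment, complications, death/deactivation) along the time axis.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.dates as mdates
import matplotlib.pyplot as plt
import pandas as pd

from .records import GroupedCase, PatientClinicalRecord, VitalStatus, chf

log = logging.getLogger(__name__)


def _month_key(date: dt.date) -> tuple[int, int]:
    return date.year, date.month


def _month_start(key: tuple[int, int]) -> dt.date:
    return dt.date(key[0], key[1], 1)


def _next_month(key: tuple[int, int]) -> tuple[int, int]:
    year, month = key
    return (year + 1, 1) if month == 12 else (year, month + 1)


@dataclass
class MonthlyCostSeries:
    patient_id: str
    fu_start: dt.date
    #: calendar-month -> cost, in chronological order of insertion
    monthly: dict[tuple[int, int], Decimal] = field(default_factory=dict)
    contributors: dict[tuple[int, int], set[str]] = field(default_factory=dict)
    #: months lying beyond the follow-up window (flagged, not dropped)
    beyond_fu: set[tuple[int, int]] = field(default_factory=set)

    def total(self) -> Decimal:
        return sum(self.monthly.values(), Decimal("0.00"))

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.monthly)
        return pd.DataFrame({
            "month": [f"{y:04d}-{m:02d}" for y, m in keys],
            "cost": [float(self.monthly[k]) for k in keys],
            "cases": ["|".join(sorted(self.contributors[k])) for k in keys],
            "beyond_fu": [k in self.beyond_fu for k in keys],
        })


def spread_costs_monthly(
    grouped_cases: list[GroupedCase],
    fu_start: dt.date,
    fu_days: int = 365,
) -> MonthlyCostSeries:
    """Spread each case's total uniformly over its span, summed monthly.

    All cases must belong to one patient.  The daily rate is
    ``total / span_days`` with the span counted inclusively, so a case
    opened and closed the same day books everything into that month.
    """
    patients = {c.patient_id for c in grouped_cases}
    if len(patients) > 1:
        raise ValueError(f"cases from several patients: {sorted(patients)}")
    series = MonthlyCostSeries(
        patient_id=patients.pop() if patients else "",
        fu_start=fu_start,
    )
    fu_end = fu_start + dt.timedelta(days=fu_days)

    for case in grouped_cases:
        span = case.span_days()
        start, end = case.first_service_date, case.last_service_date
        # inclusive day count falling into each calendar month of the span
        month_days: list[tuple[tuple[int, int], int]] = []
        key = _month_key(start)
        while True:
            m_start = max(start, _month_start(key))
            next_key = _next_month(key)
            m_end = min(end, _month_start(next_key) - dt.timedelta(days=1))
            month_days.append((key, (m_end - m_start).days + 1))
            if m_end >= end:
                break
            key = next_key

        allocated = Decimal("0.00")
        for i, (key, n_days) in enumerate(month_days):
            if i < len(month_days) - 1:
                amount = chf(case.total_cost * n_days / span)
            else:
                amount = case.total_cost - allocated  # absorb rounding residue
            allocated += amount
            series.monthly[key] = series.monthly.get(key, Decimal("0.00")) + amount
            series.contributors.setdefault(key, set()).add(case.case_number)
            if _month_start(key) >= fu_end:
                series.beyond_fu.add(key)
                log.debug(
                    "patient %s: month %s beyond follow-up end %s",
                    series.patient_id, key, fu_end,
                )
    return series


def render_profile(
    patient: PatientClinicalRecord,
    monthly_series: MonthlyCostSeries,
    utilities: pd.DataFrame | None = None,
    out_path: str | Path | None = None,
):
    """Render one patient's treatment / cost / outcome timeline figure.

    ``utilities`` is the per-assessment frame from
    :func:`vbhc.outcomes.derive_utilities`, filtered or not (rows of
    other patients are ignored).  Returns the matplotlib figure; writes
    it to ``out_path`` (SVG/PDF by extension) when given.
    """
    fig, ax_cost = plt.subplots(figsize=(10, 5))
    ax_out = ax_cost.twinx()

    keys = sorted(monthly_series.monthly)
    if keys:
        dates = [_month_start(k) for k in keys]
        values = [float(monthly_series.monthly[k]) for k in keys]
        ax_cost.fill_between(dates, values, step="post", color="0.75",
                             label="monthly cost")
    else:
        log.warning("patient %s has no cases; empty cost layer", patient.patient_id)
    ax_cost.set_ylabel("cost per month [CHF]")
    ax_cost.set_ylim(bottom=0)

    if utilities is not None and len(utilities):
        mine = utilities[utilities["patient_id"] == patient.patient_id]
        mine = mine.dropna(subset=["qlq_c30_summary_score"])
        if len(mine):
            dates = list(mine["assessment_date"])
            ax_out.plot(dates, mine["qlq_c30_summary_score"] / 100.0,
                        "o-", color="tab:blue", label="QLQ-C30 summary / 100")
            ax_out.plot(dates, mine["utility"], "s--", color="tab:cyan",
                        label="utility")
    ax_out.set_ylabel("score / utility")
    ax_out.set_ylim(0, 1.05)

    # horizontal category bands under the cost area
    bands: list[tuple[str, dt.date, dt.date, str]] = [
        ("diagnosis", patient.diagnosis_date,
         patient.diagnosis_date + dt.timedelta(days=7), "tab:purple"),
    ]
    palette = {
        "surgery": "tab:red",
        "chemotherapy": "tab:green",
        "radiotherapy": "tab:orange",
        "immunotherapy": "tab:olive",
        "targeted_therapy": "tab:pink",
    }
    for ep in patient.treatments:
        bands.append((ep.modality.value, ep.start_date, ep.end_date,
                      palette[ep.modality.value]))
    for comp in patient.complications:
        bands.append((comp.label, comp.start_date, comp.end_date, "tab:brown"))
    if patient.vital_status in (VitalStatus.DEAD, VitalStatus.DEACTIVATED):
        bands.append((patient.vital_status.value, patient.status_date,
                      patient.status_date + dt.timedelta(days=3), "black"))

    y_top = ax_cost.get_ylim()[1] or 1.0
    band_height = 0.035 * y_top
    for i, (label, start, end, colour) in enumerate(bands):
        width = max((end - start).days, 1)
        ax_cost.broken_barh(
            [(mdates.date2num(start), width)],
            (-(i + 1.6) * band_height, band_height * 0.9),
            facecolors=colour, label=label,
        )
    ax_cost.set_ylim(bottom=-(len(bands) + 2.2) * band_height)
    ax_cost.axhline(0.0, color="0.4", linewidth=0.6)

    handles, labels = ax_cost.get_legend_handles_labels()
    h2, l2 = ax_out.get_legend_handles_labels()
    seen: dict[str, object] = {}
    for h, l in zip(handles + h2, labels + l2):
        seen.setdefault(l, h)
    ax_cost.legend(seen.values(), seen.keys(), loc="upper right", fontsize=7)
    ax_cost.set_title(f"Patient {patient.patient_id}")
    fig.autofmt_xdate()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, metadata={"Date": None} if str(out_path).endswith(".svg") else None)
    return fig
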