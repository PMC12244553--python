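"""Ground-truth ledger emitted alongside synthetic datasets.

Real hospital data has no oracle: nobody knows the true cost of "the
chemotherapy" inside a shared case number.  The synthetic generator
does know, because it constructed every cost line.  The ledger records,
per case number, the true category set and the true decomposition of
the case total into drug-attributable, radiotherapy-attributable and
residual components — the reference against which the assignment
engine's output is scored.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

from .records import chf


@dataclass(slots=True)
class LedgerEntry:
    case_number: str
    patient_id: str
    categories: frozenset[str]
    #: true cost share per category (sums exactly to the case total)
    shares: dict[str, Decimal]
    #: drug-attributable component per systemic modality
    drug_components: dict[str, Decimal] = field(default_factory=dict)
    radiotherapy_component: Decimal = Decimal("0.00")
    #: labels of corruptions injected into this case (empty when clean)
    corruptions: tuple[str, ...] = ()

    @property
    def total_cost(self) -> Decimal:
        return sum(self.shares.values(), Decimal("0.00"))


@dataclass
class GroundTruthLedger:
    entries: dict[str, LedgerEntry] = field(default_factory=dict)
    #: injected cost-only case numbers with no service claims (unlinkable)
    orphan_cases: list[str] = field(default_factory=list)

    def add(self, entry: LedgerEntry) -> None:
        if entry.case_number in self.entries:
            raise ValueError(f"duplicate ledger case {entry.case_number!r}")
        self.entries[entry.case_number] = entry

    def patient_category_totals(self) -> dict[tuple[str, str], Decimal]:
        """True total cost per (patient_id, category)."""
        totals: dict[tuple[str, str], Decimal] = defaultdict(lambda: Decimal("0.00"))
        for e in self.entries.values():
            for category, share in e.shares.items():
                totals[(e.patient_id, category)] += share
        return dict(totals)

    def write(self, path: str | Path) -> None:
        """One row per (case, category) with its true cost share."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow([
                "case_number", "patient_id", "category", "cost_share",
                "drug_component", "radiotherapy_component", "corruptions",
            ])
            for case in sorted(self.entries):
                e = self.entries[case]
                for category in sorted(e.shares):
                    w.writerow([
                        e.case_number,
                        e.patient_id,
                        category,
                        f"{e.shares[category]}",
                        f"{e.drug_components.get(category, chf(0))}",
                        f"{e.radiotherapy_component if category == 'radiotherapy' else chf(0)}",
                        "|".join(e.corruptions),
                    ])
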