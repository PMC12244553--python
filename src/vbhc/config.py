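"""Default configuration shared by the generator and the assignment engine.

The rule engine is dictionary-driven: which drug names identify which
systemic therapy, which organisational-unit patterns identify surgery
and radiotherapy, and which unit prices attribute tier-1 drug costs are
all configuration, loadable from YAML.  The defaults below ship a small
representative list per modality (a platinum-doublet flavoured set for
chemotherapy, checkpoint inhibitors for immunotherapy, oral kinase
inhibitors for targeted therapy); realism of the list is a config
concern, not a code concern.
"""

from __future__ import annotations

from decimal import Decimal
from pathlib import Path

import yaml

from .assign import AssignmentRuleSet, ModalityRule
from .records import CaseType, Modality

#: CHF list price per administered unit, per drug token.  The synthetic
#: generator bills drugs at exactly these prices, and the assignment
#: engine uses the same table to attribute tier-1 drug costs.
DRUG_PRICES: dict[Modality, dict[str, Decimal]] = {
    Modality.CHEMOTHERAPY: {
        "carboplatin": Decimal("310.00"),
        "cisplatin": Decimal("260.00"),
        "pemetrexed": Decimal("1450.00"),
        "paclitaxel": Decimal("420.00"),
        "etoposide": Decimal("180.00"),
    },
    Modality.IMMUNOTHERAPY: {
        "pembrolizumab": Decimal("6850.00"),
        "atezolizumab": Decimal("5900.00"),
        "durvalumab": Decimal("5300.00"),
        "nivolumab": Decimal("4350.00"),
    },
    Modality.TARGETED_THERAPY: {
        "osimertinib": Decimal("6200.00"),
        "alectinib": Decimal("5650.00"),
        "sotorasib": Decimal("7100.00"),
    },
}

#: organisational units used by the generator, per concern
UNIT_THORACIC_SURGERY = "thoracic surgery"
UNIT_RADIO_ONCOLOGY = "radio-oncology"
UNIT_ONCOLOGY_CLINIC = "oncology outpatient clinic"

#: cost-centre types used on synthetic cost lines
CENTRE_DRUGS = "drugs"
CENTRE_RADIO = "radio-oncology"
CENTRE_WARD = "ward"
CENTRE_OR = "operating room"
CENTRE_OUTPATIENT = "outpatient clinic"
CENTRE_DIAGNOSTICS = "diagnostics"


def all_drug_unit_costs() -> dict[str, Decimal]:
    return {
        token: price
        for prices in DRUG_PRICES.values()
        for token, price in prices.items()
    }


def default_rules() -> AssignmentRuleSet:
    """Illustrative default search queries for the five modalities.

    Surgery and radiotherapy rely on unit/DRG patterns and therefore
    require a date overlap with a clinical episode; a drug-name match is
    accepted as strong evidence without one.
    """
    rules = {
        Modality.SURGERY: ModalityRule(
            modality=Modality.SURGERY,
            unit_patterns=("thoracic surgery",),
            drg_text_patterns=("lobectomy", "pneumonectomy", "thoracic surgery drg"),
            required_case_type=CaseType.INPATIENT,
            date_overlap_required=True,
        ),
        Modality.RADIOTHERAPY: ModalityRule(
            modality=Modality.RADIOTHERAPY,
            unit_patterns=("radio-oncology", "radiotherapy"),
            drg_text_patterns=("radiotherapy fraction",),
            date_overlap_required=True,
        ),
        Modality.CHEMOTHERAPY: ModalityRule(
            modality=Modality.CHEMOTHERAPY,
            drug_names=tuple(DRUG_PRICES[Modality.CHEMOTHERAPY]),
        ),
        Modality.IMMUNOTHERAPY: ModalityRule(
            modality=Modality.IMMUNOTHERAPY,
            drug_names=tuple(DRUG_PRICES[Modality.IMMUNOTHERAPY]),
        ),
        Modality.TARGETED_THERAPY: ModalityRule(
            modality=Modality.TARGETED_THERAPY,
            drug_names=tuple(DRUG_PRICES[Modality.TARGETED_THERAPY]),
        ),
    }
    return AssignmentRuleSet(
        rules=rules,
        drug_unit_costs=all_drug_unit_costs(),
        radio_cost_centre_patterns=("radio",),
    )


def rules_to_yaml(rules: AssignmentRuleSet, path: str | Path) -> None:
    doc = {
        "modalities": {
            m.value: {
                "drug_names": list(r.drug_names),
                "unit_patterns": list(r.unit_patterns),
                "drg_text_patterns": list(r.drg_text_patterns),
                "required_case_type": r.required_case_type.value
                if r.required_case_type
                else None,
                "date_overlap_required": r.date_overlap_required,
                "tolerance_days": r.tolerance_days,
            }
            for m, r in rules.rules.items()
        },
        "drug_unit_costs": {k: str(v) for k, v in rules.drug_unit_costs.items()},
        "radio_cost_centre_patterns": list(rules.radio_cost_centre_patterns),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
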