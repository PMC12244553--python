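drug_unit_costs:
  alectinib: '5650.00'
  atezolizumab: '5900.00'
  carboplatin: '310.00'
  cisplatin: '260.00'
  durvalumab: '5300.00'
  etoposide: '180.00'
  nivolumab: '4350.00'
  osimertinib: '6200.00'
  paclitaxel: '420.00'
  pembrolizumab: '6850.00'
  pemetrexed: '1450.00'
  sotorasib: '7100.00'
modalities:
  chemotherapy:
    date_overlap_required: false
    drg_text_patterns: []
    drug_names:
    - carboplatin
    - cisplatin
    - pemetrexed
    - paclitaxel
    - etoposide
    required_case_type: null
    tolerance_days: 7
    unit_patterns: []
  immunotherapy:
    date_overlap_required: false
    drg_text_patterns: []
    drug_names:
    - pembrolizumab
    - atezolizumab
    - durvalumab
    - nivolumab
    required_case_type: null
    tolerance_days: 7
    unit_patterns: []
  radiotherapy:
    date_overlap_required: true
    drg_text_patterns:
    - radiotherapy fraction
    drug_names: []
    required_case_type: null
    tolerance_days: 7
    unit_patterns:
    - radio-oncology
    - radiotherapy
  surgery:
    date_overlap_required: true
    drg_text_patterns:
    - lobectomy
    - pneumonectomy
    - thoracic surgery drg
    drug_names: []
    required_case_type: inpatient
    tolerance_days: 7
    unit_patterns:
    - thoracic surgery
  targeted_therapy:
    date_overlap_required: false
    drg_text_patterns: []
    drug_names:
    - osimertinib
    - alectinib
    - sotorasib
    required_case_type: null
    tolerance_days: 7
    unit_patterns: []
radio_cost_centre_patterns:
- radio
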