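# United States III: ATP III without the diabetes risk-equivalent rule —
# the LDL initiation threshold is selected by ten-year CHD risk stratum
# (high > 20%, moderate 10-20%, low < 10%) — with JNC 7 at 140/90.
name: United States III
initiate_at_diagnosis: []
bp_first_line: null
intensify: true
lipid_rules: []
risk_stratified: true
ldl_thresholds_by_risk: {high: 100, moderate: 130, low: 190}  # mg/dL
bp_rule: {sbp: 140, dbp: 90}
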