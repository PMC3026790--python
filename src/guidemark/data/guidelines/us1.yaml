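# United States I: ATP II lipid rule with JNC-era blood-pressure thresholds.
name: United States I
initiate_at_diagnosis: []
bp_first_line: null
intensify: true
lipid_rules:
  - {quantity: LDL, comparator: ">=", threshold: 130, unit: mg/dL}
risk_stratified: false
ldl_thresholds_by_risk: null
bp_rule: {sbp: 130, dbp: 85}
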