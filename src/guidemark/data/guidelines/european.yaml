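# European societies guideline: LDL >= 2.5 mmol/L or TC >= 4.5 mmol/L.
name: European Societies
initiate_at_diagnosis: []
bp_first_line: null
intensify: true
lipid_rules:
  - {quantity: LDL, comparator: ">=", threshold: 2.5, unit: mmol/L}
  - {quantity: TC, comparator: ">=", threshold: 4.5, unit: mmol/L}
risk_stratified: false
ldl_thresholds_by_risk: null
bp_rule: {sbp: 130, dbp: 80}
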