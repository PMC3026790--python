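# ACCORD-style intensive blood-pressure variant: lipids per ATP III
# (LDL >= 100 mg/dL), hypertension managed to a systolic target of
# 120 mm Hg (modelled as a lower initiation threshold).
name: ACCORD Intensive BP
initiate_at_diagnosis: []
bp_first_line: null
intensify: true
lipid_rules:
  - {quantity: LDL, comparator: ">=", threshold: 100, unit: mg/dL}
risk_stratified: false
ldl_thresholds_by_risk: null
bp_rule: {sbp: 120, dbp: 80}
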