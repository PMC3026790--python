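# United States IV: statin + ACE inhibitor at diagnosis, then intensify
# according to ATP III and JNC 7.
name: United States IV
initiate_at_diagnosis: [statin, ace_arb]
bp_first_line: ace_arb
intensify: true
lipid_rules:
  - {quantity: LDL, comparator: ">=", threshold: 100, unit: mg/dL}
risk_stratified: false
ldl_thresholds_by_risk: null
bp_rule: {sbp: 130, dbp: 80}
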