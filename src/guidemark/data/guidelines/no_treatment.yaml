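# Reference strategy: no medication is ever initiated.
name: No Treatment
initiate_at_diagnosis: []
bp_first_line: null
intensify: false
lipid_rules: []
risk_stratified: false
ldl_thresholds_by_risk: null
bp_rule: null
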