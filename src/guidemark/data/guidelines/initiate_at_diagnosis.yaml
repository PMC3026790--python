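# Risk-blind reference strategy: statin + ACE inhibitor at diagnosis, with
# no further measurement or intensification.
name: Initiate at Diagnosis
initiate_at_diagnosis: [statin, ace_arb]
bp_first_line: ace_arb
intensify: false
lipid_rules: []
risk_stratified: false
ldl_thresholds_by_risk: null
bp_rule: null
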