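# UKPDS risk-engine coefficients for first CHD event (UKPDS 56) and first
# stroke (UKPDS 60), transcribed from the published equations.  The annual
# hazard for a patient with diabetes duration t years is
#
#     h(t) = q0 * prod_i coef_i ^ x_i * d ^ t
#
# where each x_i is a centred (and possibly log-transformed or rescaled)
# covariate, and the annual event probability is 1 - exp(-h(t)).
# Covariate kinds:
#   binary -> x = 0/1 flag
#   linear -> x = (value - center) / scale
#   log    -> x = ln(value) - center
chd:
  q0: 0.0112
  d: 1.078
  covariates:
    - {name: age_at_diagnosis, kind: linear, coef: 1.059, center: 55.0, scale: 1.0}
    - {name: female, kind: binary, coef: 0.525}
    - {name: afro_caribbean, kind: binary, coef: 0.390}
    - {name: smoker, kind: binary, coef: 1.350}
    - {name: hba1c, kind: linear, coef: 1.183, center: 6.72, scale: 1.0}
    - {name: sbp, kind: linear, coef: 1.088, center: 135.7, scale: 10.0}
    - {name: lipid_ratio, kind: log, coef: 3.845, center: 1.59}
stroke:
  q0: 0.00186
  d: 1.145
  covariates:
    - {name: age_at_diagnosis, kind: linear, coef: 1.092, center: 55.0, scale: 1.0}
    - {name: female, kind: binary, coef: 0.700}
    - {name: smoker, kind: binary, coef: 1.547}
    - {name: atrial_fibrillation, kind: binary, coef: 8.554}
    - {name: hba1c, kind: linear, coef: 1.122, center: 6.72, scale: 1.0}
    - {name: sbp, kind: linear, coef: 1.122, center: 135.5, scale: 10.0}
    - {name: lipid_ratio, kind: linear, coef: 1.138, center: 5.11, scale: 1.0}
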