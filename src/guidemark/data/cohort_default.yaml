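# Default synthetic-cohort configuration.  Scale parameters (663 patients,
# ~15,000 visit records over a 10-year window, ~1.7% deaths during
# observation) mirror the published source cohort; all distributional
# parameters (means, spreads, drifts, persistence) are package choices
# representing a plausible middle-aged type 2 diabetes population and are
# documented as such.
n_patients: 663
age_range: [40, 80]
years_observed: 10
visit_rate: 2.2          # mean visits per patient-year
sex_ratio: 0.53          # fraction male
baseline_means:
  TC: 200.0              # mg/dL
  HDL: 45.0              # mg/dL
  TG: 160.0              # mg/dL
  SBP: 135.0             # mm Hg
  DBP: 80.0              # mm Hg
  HBA1C: 7.2             # %
baseline_sds:
  TC: 35.0
  HDL: 12.0
  TG: 55.0
  SBP: 16.0
  DBP: 10.0
  HBA1C: 1.1
annual_drift:            # mean change per year of age
  TC: 0.5
  HDL: -0.1
  TG: 1.0
  SBP: 0.5
  DBP: 0.1
  HBA1C: 0.03
persistence:             # one-year autocorrelation of the latent AR(1)
  TC: 0.85
  HDL: 0.85
  TG: 0.85
  SBP: 0.85
  DBP: 0.85
  HBA1C: 0.85
death_rate_other: 0.0017 # annual probability of death from other causes
seed: 12345
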