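# Percent change in metabolic factors on initiation of each medication
# class (negative = reduction), estimated from observational initiation
# episodes.  Lipid-lowering classes touch only TC/HDL, antihypertensives
# only SBP/DBP.
statin:
  TC: -14.0
  HDL: 7.3
fibrate:
  TC: -3.9
  HDL: 4.7
ace_arb:
  SBP: -3.7
  DBP: -5.5
thiazide:
  SBP: -5.0
  DBP: -3.7
beta_blocker:
  SBP: -4.6
  DBP: -4.2
ccb:
  SBP: -2.5
  DBP: -4.8
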