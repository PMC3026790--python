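# Annual medication costs in US dollars (2009 Red Book wholesale prices).
# base: lowest listed price per class (generic); upper: highest listed
# price (branded).
base:
  statin: 212
  fibrate: 652
  ace_arb: 48
  thiazide: 48
  beta_blocker: 48
  ccb: 866
upper:
  statin: 1258
  fibrate: 1452
  ace_arb: 868
  thiazide: 946
  beta_blocker: 145
  ccb: 1031
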