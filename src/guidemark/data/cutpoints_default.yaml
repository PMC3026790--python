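# Default bin structure for the binned risk-factor Markov chains.
# Edges are in mg/dL (TC, HDL) and mm Hg (SBP, DBP).  Blood-pressure
# guideline thresholds (120/130/140/160 systolic, 80/85/90 diastolic) all
# fall on bin boundaries so initiation rules are exactly representable on
# binned states.  These defaults are package choices and fully overridable.
TC:
  edges: [160, 200, 240]
  representatives: [140, 180, 220, 260]
HDL:
  edges: [35, 45, 60]
  representatives: [30, 40, 52.5, 70]
SBP:
  edges: [120, 130, 140, 160]
  representatives: [110, 125, 135, 150, 170]
DBP:
  edges: [80, 85, 90]
  representatives: [70, 82.5, 87.5, 95]
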