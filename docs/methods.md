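# Methods

## Model structure

The natural-history model is a discrete-time Markov cohort model with
annual cycles from age 40 to 80. A live health state is the product of

- four binned risk factors — total cholesterol (TC), HDL cholesterol,
  systolic (SBP) and diastolic (DBP) blood pressure — each evolving as an
  independent, stationary annual Markov chain on a small number of bins,
- progress along two fixed medication sequences: lipid (statin, then
  fibrate) and blood pressure (thiazide, ACE/ARB, β-blocker, CCB; ACE/ARB
  first for the initiate-at-diagnosis variants).

Triglycerides (TG) and HbA1c enter as deterministic linear functions of
age fitted from panel data, clamped to the fitted age range. Three
absorbing exits compete each cycle: first CHD event, first stroke, and
death from other causes. The model is primary-prevention only: nothing is
modelled after the first event.

Key behavioural assumptions: treatment decisions are revisited once per
year; at most one new medication class per domain starts per year;
medications are never discontinued (perfect adherence); effects of classes
acting on the same factor are additive in percent terms; lipid and
blood-pressure drugs do not interact across domains.

## Cycle order

The cycle order is: guideline decision → treated factor values → event and
death risks → competing-risk absorption → factor bin transitions → cost
accrual. A year's newly started medication therefore affects that same
year's risk, matching initiation "whenever the patient meets the
criteria". Costs are charged at the newly decided medication set for all
mass alive and event-free at the start of the cycle, discounted to age 40
at 3%/year; there is no half-cycle correction. Factor values entering the
rules and risk equations are bin representatives (interior bin midpoints;
pragmatic values for the open-ended outer bins), since the engine is
bin-resolved.

## Parameters

- **Bin edges** (overridable configuration): TC 160/200/240, HDL 35/45/60
  mg/dL; SBP 120/130/140/160, DBP 80/85/90 mm Hg. All blood-pressure
  guideline thresholds coincide with bin edges, so BP initiation rules are
  exactly representable on binned states; lipid rules are evaluated on
  continuous derived quantities (Friedewald LDL, TC:HDL ratio) at the bin
  representatives, so exact edge alignment is not required there.
- **Medication effects** (percent change on initiation): statin −14 TC,
  +7.3 HDL; fibrate −3.9 TC, +4.7 HDL; ACE/ARB −3.7 SBP, −5.5 DBP;
  thiazide −5.0 SBP, −3.7 DBP; β-blocker −4.6 SBP, −4.2 DBP; CCB −2.5 SBP,
  −4.8 DBP.
- **Annual costs** (US$, 2009 Red Book): base case (lowest generic price)
  statin 212, fibrate 652, ACE/ARB 48, thiazide 48, β-blocker 48, CCB 866;
  upper bound (branded) 1258/1452/868/946/145/1031.
- **Risk engines**: UKPDS-form hazards, CHD from the UKPDS 56 engine and
  stroke from the UKPDS 60 engine, transcribed into
  `data/ukpds_coefficients.yaml`. The file is plain configuration:
  swapping in a different coefficient file changes risks without code
  changes. The test suite validates structural properties (positivity,
  monotonicity in duration and lipid ratio, sex ordering), not the
  transcribed constants.
- **Other-cause mortality**: a synthetic Gompertz-shaped life table,
  `q(age) = q40 · exp(0.082 · (age − 40))` with q40 = 0.0025 (male) and
  0.0015 (female), capped at 1 and covering ages 40–100. This is an
  invented smooth default with realistic orders of magnitude, not a
  national life-table extract; `MortalityTable.from_csv` loads a real
  table. All-cause rates are used as-is, with no decrement for CHD/stroke
  deaths — a simplification that slightly double-counts cardiovascular
  mortality in the competing-risk split.
- **Discount rate**: 3%/year for costs, year 0 undiscounted.

## Guideline encodings

The nine guideline combinations plus the ACCORD-style intensive-BP variant
ship as YAML. Choices made where the printed rules are ambiguous:

- US I uses the printed thresholds (LDL ≥ 130 mg/dL; SBP > 130 or DBP > 85).
- "LR ≥ 4" (Canada) is read as TC:HDL ratio ≥ 4.
- The Australian TC threshold is garbled in the source; it defaults to
  4.0 mmol/L (matching the British TC rule) and is configurable.
- US III selects its LDL threshold (100/130/190 mg/dL) by the model's own
  ten-year CHD risk — the UKPDS hazard accumulated over ten cycles with
  factors frozen — with strata >20%, 10–20%, <10%; no external risk
  calculator is referenced.
- Blood-pressure comparisons are strict (`>`), lipid comparisons inclusive
  (`≥`), following the printed rules; the ACCORD variant triggers at
  SBP > 120 mm Hg.
- Initiation thresholds are the only intensification check (no
  treat-to-goal logic beyond them), and the lipid predicates combine as
  "any triggers".

Outcome measures use the whole-cohort denominator by default
(NNT = 1/ARR; events avoided per 1,000 = 1000·ARR, so NNT × events
avoided = 1000 exactly); a per-ever-treated denominator is available as an
option. "Events" are CHD and stroke combined; other-cause death is a
separate absorbing state, not an event.

## Synthetic cohort generator

The generator emulates a single-institution diabetes registry: 663
patients entering at uniform ages, observed 10 years with one scheduled
visit per year plus Poisson extras (≈2.2 visits/patient-year, ≈15,000
records), 53% male, and an annual other-cause death rate of 0.0017
(≈1.7% dying during the window, censoring later visits). Factor
trajectories are latent untreated continuous-time AR(1) processes around
age-drifting means — over a gap of `dt` years the autocorrelation is
`ρ^dt` with `ρ = 0.85`/year — so annually sampled binned values are
approximately first-order Markov, which is what the transition estimator
assumes. Baseline means/SDs (TC 200±35, HDL 45±12, TG 160±55 mg/dL, SBP
135±16, DBP 80±10 mm Hg, HbA1c 7.2±1.1%) and drifts are package choices
representing a plausible middle-aged type 2 diabetes population.

Treatment injection (`inject_treatment_starts`) overlays per-class
multiplicative effects `1 + (pct + ε)/100` (ε per episode, 1 percentage
point SD) from the start visit onward; multipliers of different classes
compound, which keeps each class's percent effect identifiable from
pre/post ratios even when other classes are already active. The cohort
engine, by contrast, applies the additive-percent convention when
computing treated values, which is the model's stated treatment-effect
assumption; at the effect sizes involved the two conventions differ by
well under one percent.

What the generator does **not** emulate: real visit-scheduling and
missingness patterns, measurement error distinct from biological
variation, cross-factor correlation, informative dropout, medication
titration, or event feedback onto risk factors. Passing tests therefore
establish internal correctness of the estimators and engine under the
model's own assumptions, not fidelity to any real registry.

## Numerical and statistical choices

- Bins are half-open `[eᵢ, eᵢ₊₁)`; a value on an interior edge belongs to
  the higher bin; the outer bins are unbounded.
- Transition estimation uses the first measurement per patient-year;
  only consecutive-year pairs contribute; gaps longer than a year split
  the sequence (no interpolation). A pseudo-count of 0.5 per cell avoids
  spurious absorbing states in sparse panels; with no data and no
  smoothing a row falls back to uniform.
- The panel stores an integer `visit_year` per record; with more than one
  visit per year the within-patient ordering invariant is enforced as
  non-decreasing `visit_year` with strictly increasing age.
- Competing risks: independent exit probabilities are combined as
  `P_any = 1 − ∏(1 − pᵢ)` and split proportionally to hazards
  `−log(1 − pᵢ)`; probabilities are clipped below 1 by 1e−15 before the
  log. Outputs sum to 1 to 1e−12.
- Mass conservation (live + absorbed = 1) is asserted at every age to
  1e−9 by the engine itself.
- The treatment-effect estimator (mean per-episode percent change,
  confounded episodes excluded) carries a small positive finite-sample
  bias of order `(1 − ρ^dt) · cv²` from mean reversion between the pre-
  and post-start visits (≈0.2–0.5 percentage points for the spreads
  above). At registry scale this is well inside sampling error; at much
  larger sample sizes it would dominate the shrinking standard error, so
  recovery checks are run at registry scale with a realistic 10%/year
  initiation rate.
- The microsimulation oracle (default 50,000 patients in acceptance runs)
  shares the decision, risk and cost code paths with the exact engine but
  replaces expectation propagation with per-patient draws from a single
  seeded generator; agreement is checked within 3 Monte-Carlo SEs.

## Known limitations

- DBP is modelled as a fourth independent Markov chain for uniformity,
  although only TC, HDL and SBP dynamics are usually described that way;
  DBP still drives thresholds and treatment effects.
- The four chains are independent and time-homogeneous; real lipid and
  blood-pressure trajectories are correlated and age-dependent.
- UKPDS hazard growth (`d^t`) is extrapolated to 40 years of diabetes
  duration, well beyond the trial's follow-up; absolute late-life stroke
  risks are accordingly generous.
- Headline absolute results depend on the synthetic cohort and the
  synthetic life table; only internal-consistency and structural claims
  are asserted quantitatively, and cross-guideline *orderings* (not
  absolute levels) are the meaningful output.
- Adverse effects, non-adherence, discontinuation, revascularization,
  glycemic-control costs and quality-of-life weighting are all out of
  scope by design.
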