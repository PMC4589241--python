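# Methods

`chdprevent` is an annual-cycle state-transition (Markov) microsimulation
comparing eight primary-prevention strategies for coronary heart disease
(CHD) in a closed cohort of asymptomatic, non-diabetic US adults — men
45–75 and women 55–75 — followed for 30 years or until death. This note
documents the model, its inputs and their provenance, the numerical
choices, and what the synthetic population does and does not emulate.

## Model structure

Each simulated person occupies one of four states: alive without CHD,
alive post-MI, dead of CHD, dead of other causes, with persistent flags for
post-hemorrhagic-stroke, statin-associated diabetes, radiation-attributable
cancer, and revascularisation. Within a cycle the order of operations is

1. non-CHD death (age/sex life table),
2. CHD event — first events only; fatal with probability `mi_case_fatality`,
3. medication harms (aspirin bleeding/stroke), therapy costs and utilities.

Persons accrue nothing in the year they die; no half-cycle correction is
applied (the reference model is silent on both, and at a 3% discount rate
the half-cycle term is small relative to the sampling noise at desk scale).
Costs (2010 US$) and QALYs are discounted at 3%/year; year 0 is
undiscounted. Results are extrapolated to the 2010 target population of
46.9M men and 27.3M women.

### Annual CHD risk

The 10-year Framingham risk (FRS) is converted to an annual probability by
constant-hazard decomposition, `p = 1 − (1 − FRS₁₀)^(1/10)`. Risk
modifiers combine multiplicatively (a proportional-hazards-style
assumption):

- **Marker relative risks.** When a strategy measures coronary calcium
  (CAC) or C-reactive protein (CRP), the published category relative risks
  (CAC: 1 / 1.9 / 4.3 / 7.2 / 10.8; CRP: two FRS-stratified ladders) are
  applied to the tested persons after renormalisation within
  (sex × 10-year age band × FRS category) strata. The stratum normaliser is
  solved (Brent's method, tolerance 1e-12) so that the stratum's *expected
  number of first CHD events over the full horizon*, weighted by
  background survival, is unchanged: measuring a marker redistributes risk
  across people without inflating or deflating it. Annual-scale
  conservation alone is insufficient because 30-year cumulative first-event
  incidence is concave in the annual probability; an annual-scale
  normaliser loses ~13% of events in the screening arms, which the
  horizon-scale solve eliminates (this is what makes the null-treatment
  equivalence property hold).
- **Statins.** Every 1 mg/dl of LDL-C lowered removes 0.6% of the person's
  CHD risk. The LDL-C drop is 34% of baseline (moderate intensity,
  atorvastatin 10), 55% (high intensity, atorvastatin 80), or a flat
  47 mg/dl (rosuvastatin 20). The relative risk is floored at 0.10 (the
  linear rule turns negative above ~150 mg/dl of reduction). In low-risk
  persons (FRS < 10%; the reference never defines the cut, 10% matches its
  other branching) the risk *reduction* is attenuated by 19% (up to 60% in
  sensitivity analyses).
- **Aspirin.** Relative risk 0.77 for treated men; 1.0 for women (no
  demonstrated primary-prevention benefit), who are never prescribed it.
- **Adherence.** 84% at baseline, drawn once per person at therapy start
  and persistent (motivated by early statin intolerance and
  discontinuation). Non-adherent persons get no benefit and accrue no
  ongoing therapy costs or disutility; one-time initiation adverse events
  still apply (see below).

### Harms

Statin initiation adverse events (hepatitis 0.0135, liver failure 6.1e-5,
myopathy 0.0074, rhabdomyolysis 5.9e-5, new diabetes 0.003 at high
intensity; roughly half at moderate, with diabetes printed as 0.001) are
drawn **once per initiator** by default (`adverse_event_mode: once`).
Rationale: the reference's own population totals (≈1.04M hepatitis cases
among ≈74.2M treated at "annual incidence" 0.0135) equal population ×
incidence × ≈1, which is inconsistent with 30 independent annual draws; the
alternative interpretation remains available as `adverse_event_mode:
annual`. A single uniform per person per event type means a later dose
escalation can only add the incremental probability. Diabetes carries a
lifelong 0.12 utility decrement; the other events are one-time cost/QALY
hits. Statin use also carries a per-year disutility (0.00054 high / 0.00023
moderate) plus the expected intolerance decrement (0.175 × 0.00028, applied
as its expectation rather than a draw).

Aspirin harms while on therapy: GI bleeding 1.42e-4/year (per-episode cost
and 0.06 decrement) and hemorrhagic stroke 2e-4/year (one-time cost,
lifelong 0.351 decrement).

CAC scanning (2.3 mSv effective) induces lagged cancers — lung, breast
(women), leukemia — at the published per-sex risks per scan, scaled
linearly in dose and mildly declining in exposure age (risk tables print
only anchor ages; the decline is a documented provisional choice). Solid
tumours onset 10 years after exposure, leukemia after 2; each cancer
carries a lifetime cost at onset and state-utility multipliers (lung 0.42
first year then 0.65; breast 0.7; leukemia 0.85 for 3 years then 0.56).

### The stress-test cascade (CAC > 400)

Everyone with CAC > 400 in a calcium-score strategy undergoes nuclear
stress testing ($878.42, 0.0006 QALY decrement, 4.5e-5 cancer risk per
test). With probability 0.31 the test shows moderate/severe ischemia,
leading to angiography ($2,585) and, among those, PCI (33%, $16,795,
−0.14 utility for one month) or CABG (19%, $44,820, −0.16 for 2.5 months).
Ischemic persons' FRS-based risk is replaced by the published annual rates
(mortality 5.2%, MI 3.1%), reduced by revascularisation (−2.3% and −1.4%
respectively). A negative stress test leaves the person on the <70 mg/dl
LDL goal.

## Strategies

All strategies except status quo and treat-all give aspirin to men with
FRS > 10%; treat-all gives it to all men. Goal-titration picks the minimum
statin intensity whose expected LDL drop reaches the goal (none if already
below goal; high intensity best-effort if even 55% cannot reach it).

Persons below a strategy's age window at entry (men < 50 / women < 60 for
the CAC and CRP strategies) follow the LDL-goal rule in the interim and are
risk-stratified **once** upon reaching the window age. This deferred
stratification — not repeat testing — is required to reproduce the
published scan totals (≈47M SHAPE scans among 46.9M men is only possible if
45–49-year-olds are scanned when they turn 50).

## Inputs and provenance

All parameters live in `src/chdprevent/data/` as YAML/CSV and are
overridable. Two provenance classes:

**Printed values** (used verbatim): treatment effects, adverse-event
incidences/costs/disutilities, MI costs and utilities, CAC/CRP relative
risks and costs, CRP medians with 95% intervals per FRS stratum,
status-quo statin/aspirin use by age/sex, radiation anchors, cascade
parameters, discount rate, population sizes.

**Provisional tables** (the primary source's supplement is not available;
these are surrogates calibrated analytically to population facts its main
text does print, before any model run, and frozen):

- *FRS distribution by age/sex* — calibrated to: 16% of men and 66% of
  women with FRS < 5%; ≈52% of men and ≈5.5% of women with FRS > 10%
  (implied by the Texas-law scan counts); and the national 30-year CHD
  validation totals. The top category spans 20–40% 10-year risk;
  within-category risk is uniform (a choice, not source-derived).
- *LDL-C by sex and FRS* — truncated normals (30–400 mg/dl) whose means
  reproduce the goal-titration statin shares (31.0% men / 17.5% women) and
  rise with FRS. They place older women above men in marginal mean, which
  matches survey data for these age windows even though the source
  describes women as having lower LDL-C *at equal age* — an age-conditional
  statement a (sex, FRS)-only table cannot encode.
- *FRS→PCE map* — sex-specific proportional piecewise-linear maps anchored
  so the 7.5% PCE threshold reproduces the risk-based guideline's statin
  shares (46.2% men / 21.5% women).
- *CAC category distribution by age/sex*, *prevalence of ≥1 SHAPE risk
  factor* (calibrated to the scan totals; ~0.99 for men since the SHAPE
  risk-factor list covers nearly all middle-aged men), and a *Gompertz
  non-CHD life table*.

MI case fatality (0.30) is a structural assumption, not a published input:
the source never states the fatal/non-fatal split, and CHD mortality is
otherwise folded into it.

## Probabilistic sensitivity analysis

The PSA jointly varies exactly the parameters the reference lists: statin
LDL drops, the aspirin relative risk, statin/intolerance disutilities, the
low-risk attenuation (beta distributions moment-matched to the printed
ranges treated as central 95% intervals), and radiation dose plus
CAC/aspirin/statin costs (log-normals with the printed median and 95%
range). Each replicate reruns a reduced cohort per strategy with common
random numbers; acceptability curves report, per willingness-to-pay point,
the fraction of replicates in which each strategy maximises net monetary
benefit (the statistic is a choice; the reference shows the curves without
naming one). Default desk-scale sizes: 10,000 persons × 250 replicates in
the library, 4,000 × 60 in the acceptance script.

## Randomness and reproducibility

All generators are counter-based (Philox) with keys derived from the run
seed. Year-loop draws follow a fixed order independent of the strategy, so
strategies simulated with the same seed share event uniforms (common random
numbers), and results are independent of iteration order. Identical
(config, seed) reruns are byte-identical; every output file carries the
seed and a configuration hash.

## Problem sizes

Point estimates in the test suite use 40,000 persons per sex (per-person
mean QALY differences then carry a Monte-Carlo SE of roughly 0.01, i.e.
≈0.5M QALYs at population scale); the acceptance script uses 100,000 per
sex. These are desk-scale choices; all sizes are configurable and scale
linearly in runtime (~0.1 s per strategy-year per 100k persons).

## What the synthetic population does not emulate

No within-person correlation between CAC and FRS beyond age/sex
conditioning; no correlation between CRP and LDL-C; no repeat testing or
dynamic cohort entry; no recurrent MI beyond the post-MI cost/utility
state; no ischemic-stroke benefit of statins; no competing-disease dynamics
beyond background mortality; FRS is assigned once and not re-computed with
age. Passing tests therefore demonstrate the internal consistency of the
model under these stated conditions, not the joint realism of the
underlying risk-factor distributions.

## Known limitations

With the supplement's input tables unavailable, the headline *magnitudes*
of the treat-all comparison (MIs prevented, dollars saved) are not fully
reproducible: reproducing the published savings requires a larger
prevented-event fraction and larger per-MI cost streams than the printed
effect sizes and MI costs yield under input tables that simultaneously
reproduce the published statin shares. The package reproduces the
validation anchors, adverse-event totals, scan counts, statin shares,
number-needed-to-harm and acceptability statements well, and the
qualitative orderings (risk-based guideline beats goal-titration; targeted
CAC beats population screening on harms; treat-all high-dose is the most
effective and most cost-effective arm at $50,000/QALY), but treat-all does
not strictly dominate every alternative in this cost accounting, and at
1000× statin disutility the status quo rejoins the frontier for men while
statin-lighter arms overtake it for women.
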