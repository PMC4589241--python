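# Model parameters (point values and probabilistic-sensitivity ranges).
# Costs are 2010 US dollars; probabilities are annual unless noted.
discount_rate: 0.03
horizon_years: 30
population:
  male: 46.9e+6
  female: 27.3e+6
# One-time initiation draws ("once") or independent annual draws ("annual")
# for statin-associated adverse events.
adverse_event_mode: once
# Fraction of incident MIs that are immediately fatal. Not a published model
# input; structural assumption (see docs/methods.md).
mi_case_fatality: 0.30
adherence: 0.84

aspirin:
  rr_chd_male: 0.77          # range 0.67-0.89 (beta)
  rr_chd_female: 1.0
  annual_cost: 7.00          # range 2-16 (log-normal)
  gi_bleed:
    annual_incidence: 1.42e-4   # range 0-3.6e-4 (beta)
    qaly_decrement: 0.06        # per episode
    cost: 4100.0                # per episode
  hemorrhagic_stroke:
    annual_incidence: 2.0e-4
    qaly_decrement: 0.351       # lifelong, per year
    cost: 35618.0

statin:
  chd_rr_per_mg_ldl: 0.006   # relative risk reduction per 1 mg/dl LDL-C lowered
  rr_floor: 0.10             # structural floor on the statin relative risk
  low_risk_attenuation: 0.19 # efficacy reduction in low-risk persons; PSA up to 0.60
  low_risk_frs_threshold: 0.10
  intolerance:
    incidence: 0.175
    qaly_decrement: 2.8e-4   # range 6.8e-5-5.5e-4 (beta); applied as expectation
  moderate:
    agent: atorvastatin10
    ldl_drop_fraction: 0.34  # range 0.27-0.38 (beta)
    annual_cost: 83.81       # range 35.03-189.55 (log-normal)
    disutility: 2.3e-4       # per year on therapy; range 1.0e-4-4.9e-4 (beta)
    adverse_events:
      hepatitis:       {incidence: 0.00675,  qaly_decrement: 3.5e-5,  cost: 36.39}
      liver_failure:   {incidence: 3.05e-5,  qaly_decrement: 0.0262,  cost: 15729.0}
      myopathy:        {incidence: 0.0037,   qaly_decrement: 0.0164,  cost: 28.41}
      rhabdomyolysis:  {incidence: 2.95e-5,  qaly_decrement: 0.0852,  cost: 11745.0}
      diabetes:        {incidence: 0.001,    qaly_decrement: 0.12,    cost: 6357.0}
  high:
    agent: atorvastatin80
    ldl_drop_fraction: 0.55  # range 0.51-0.59 (beta)
    annual_cost: 85.38       # range 35.28-195.77 (log-normal)
    disutility: 5.4e-4       # range 2.4e-4-1.2e-3 (beta)
    adverse_events:
      hepatitis:       {incidence: 0.0135,   qaly_decrement: 3.5e-5,  cost: 36.39}
      liver_failure:   {incidence: 6.1e-5,   qaly_decrement: 0.0262,  cost: 15729.0}
      myopathy:        {incidence: 0.0074,   qaly_decrement: 0.0164,  cost: 28.41}
      rhabdomyolysis:  {incidence: 5.9e-5,   qaly_decrement: 0.0852,  cost: 11745.0}
      diabetes:        {incidence: 0.003,    qaly_decrement: 0.12,    cost: 6357.0}
  rosuvastatin:
    agent: rosuvastatin20
    ldl_drop_mg: 47.0        # absolute LDL-C drop, mg/dl
    annual_cost: 1341.0      # branded, through model year 5 (2011-2016); range 898-1735
    annual_cost_generic: 83.0
    generic_from_year: 6
    disutility: 5.4e-4
    adverse_events:          # high-intensity profile
      hepatitis:       {incidence: 0.0135,   qaly_decrement: 3.5e-5,  cost: 36.39}
      liver_failure:   {incidence: 6.1e-5,   qaly_decrement: 0.0262,  cost: 15729.0}
      myopathy:        {incidence: 0.0074,   qaly_decrement: 0.0164,  cost: 28.41}
      rhabdomyolysis:  {incidence: 5.9e-5,   qaly_decrement: 0.0852,  cost: 11745.0}
      diabetes:        {incidence: 0.003,    qaly_decrement: 0.12,    cost: 6357.0}

statin_care_annual_cost:
  physician_visits: 65.30
  laboratory: 30.32

mi:
  cost_upfront: 25567.0
  cost_annual: 3109.0
  utility_first_8_days: 0.829
  utility_annual: 0.865

cac:
  cost: 200.0                # range 100-400 (log-normal)
  effective_dose_msv: 2.3
  rr_by_category:            # relative risk of CHD vs the cohort
    "0": 1.0
    "1-100": 1.9
    "101-400": 4.3
    "401-1000": 7.2
    ">1000": 10.8

crp_test_cost: 19.0
crp_rr:                      # relative risk of CHD by CRP band, stratified on FRS
  frs_lt10:
    "<0.5": 1.0
    "0.5-1": 1.9
    "1-3": 2.0
    "3-10": 3.1
    ">10": 4.5
  frs_ge10:
    "<0.5": 1.0
    "0.5-1": 1.2
    "1-3": 2.2
    "3-10": 2.5
    ">10": 4.8

stress_cascade:              # persons with CAC > 400 (SHAPE / Texas)
  stress_test:
    cost: 878.42
    qaly_decrement: 6.0e-4
    cancer_risk: 4.5e-5      # per test
    cancer_cost: 93777.0
    cancer_qaly_lost: 12.3
  p_moderate_severe_ischemia: 0.31
  angiography_cost: 2585.0
  p_pci: 0.33                # among moderate/severe ischemia
  p_cabg: 0.19
  pci:  {cost: 16795.0, qaly_decrement: 0.011667}   # 0.14 for one month
  cabg: {cost: 44820.0, qaly_decrement: 0.033333}   # 0.16 for 2.5 months
  ischemia_annual_mortality: 0.052
  ischemia_annual_mi: 0.031
  revasc_mortality_reduction: 0.023
  revasc_mi_reduction: 0.014

radiation:
  reference_dose_msv: 2.3    # cancer risks scale linearly in dose / reference
  lag_years: {solid: 10, leukemia: 2}
  cancers:
    lung:     {cost: 56624.0, utility_first_year: 0.42, utility_later: 0.65,
               first_phase_years: 1}
    breast:   {cost: 37306.0, utility_first_year: 0.70, utility_later: 0.70,
               first_phase_years: 1}
    leukemia: {cost: 98000.0, utility_first_year: 0.85, utility_later: 0.56,
               first_phase_years: 3}

# Probabilistic sensitivity analysis: parameter path -> family and 95% range.
# beta: moment-matched on the native scale; lognormal: median + 95% range.
psa:
  - {path: statin.moderate.ldl_drop_fraction, family: beta,      lo: 0.27,    hi: 0.38}
  - {path: statin.high.ldl_drop_fraction,     family: beta,      lo: 0.51,    hi: 0.59}
  - {path: aspirin.rr_chd_male,               family: beta,      lo: 0.67,    hi: 0.89}
  - {path: statin.moderate.disutility,        family: beta,      lo: 1.0e-4,  hi: 4.9e-4}
  - {path: statin.high.disutility,            family: beta,      lo: 2.4e-4,  hi: 1.2e-3}
  - {path: statin.intolerance.qaly_decrement, family: beta,      lo: 6.8e-5,  hi: 5.5e-4}
  - {path: statin.low_risk_attenuation,       family: beta,      lo: 0.0,     hi: 0.60}
  - {path: cac.effective_dose_msv,            family: lognormal, lo: 0.2,     hi: 10.0}
  - {path: cac.cost,                          family: lognormal, lo: 100.0,   hi: 400.0}
  - {path: aspirin.annual_cost,               family: lognormal, lo: 2.0,     hi: 16.0}
  - {path: statin.moderate.annual_cost,       family: lognormal, lo: 35.03,   hi: 189.55}
  - {path: statin.high.annual_cost,           family: lognormal, lo: 35.28,   hi: 195.77}
  - {path: statin.rosuvastatin.annual_cost,   family: lognormal, lo: 898.0,   hi: 1735.0}
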