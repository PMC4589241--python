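# chdprevent

A state-transition (Markov) microsimulation for comparing the
cost-effectiveness of primary-prevention strategies for coronary heart
disease (CHD) in the asymptomatic US adult population (men 45–75, women
55–75, diabetics excluded). It is aimed at health-economics and
cardiovascular-epidemiology researchers who want a fully scriptable,
seeded, plain-text-configured implementation of the classic
"risk-stratify vs treat-all" comparison.

Eight strategies are modelled:

| strategy | rule |
|---|---|
| `status_quo` | observed statin/aspirin use by age and sex (comparator) |
| `atp3` | LDL-C goal titration by Framingham risk (<160 / <130 / <100 mg/dl) |
| `accaha` | high-intensity statin if Pooled-Cohort risk ≥ 7.5% (LDL-C 70–190), always above 190 |
| `jupiter` | rosuvastatin 20 mg if CRP > 2 mg/L and LDL-C < 130 (men ≥ 50 / women ≥ 60) |
| `shape` | population CAC screening; LDL goal by calcium score; stress-test cascade above 400 |
| `texas` | CAC only for FRS > 10%, otherwise goal titration |
| `treat_all_moderate` / `treat_all_high` | atorvastatin 10/80 mg for everyone, aspirin for all men |

## The model in brief

Each person carries fixed baseline attributes (age, sex, 10-year
Framingham risk FRS₁₀, LDL-C, CAC category, CRP) drawn from configurable
distribution tables. The annual CHD hazard is

```
p = 1 − (1 − FRS₁₀)^(1/10)
```

multiplied by (i) a marker relative risk when the strategy measured CAC or
CRP, renormalised within strata so that expected first events over the
horizon are conserved, (ii) a statin relative risk
`max(1 − 0.006·ΔLDL, 0.10)` with ΔLDL = 34%/55% of baseline (or 47 mg/dl
flat for rosuvastatin) and a 19% efficacy attenuation below FRS 10%, and
(iii) an aspirin relative risk of 0.77 for treated men. Events are fatal
with probability 0.30; survivors enter a post-MI state ($25,567 upfront,
$3,109/year, utility 0.865). Statin initiation carries one-time
adverse-event draws (hepatitis, liver failure, myopathy, rhabdomyolysis,
diabetes) and a per-year disutility; aspirin carries bleeding and
hemorrhagic-stroke hazards; CAC scans carry lagged radiation-cancer risks.
Costs (2010 US$) and QALYs are discounted at 3%/year over 30 years and
scaled to 46.9M men / 27.3M women. Strategies are compared by incremental
cost-effectiveness ratios, a dominance/efficiency frontier, probabilistic
sensitivity analysis with acceptability curves, and NNT/NNH. See
`docs/methods.md` for the full account, including which input tables are
transcribed from published values and which are documented provisional
surrogates.

## Worked example

```python
import chdprevent as cp

tables = cp.default_tables()          # packaged distribution tables (CSV)
params = cp.default_parameters()      # packaged parameter set (YAML)

cfg = cp.RunConfig(n_per_sex=30_000, seed=1)
results = cp.run_all_strategies(cfg, params, tables)   # {sex: {strategy: CohortResult}}

men = results["male"]
sq, th = men["status_quo"], men["treat_all_high"]
f = 46.9e6 / sq.n_simulated          # scale to the male target population
print(f"MIs prevented : {f*(sq.counts['chd_events']-th.counts['chd_events'])/1e6:.2f} M")
print(f"QALYs gained  : {f*(th.qaly_discounted-sq.qaly_discounted)/1e6:.2f} M")
print(cp.config.frontier_for(men).table[['strategy','mean_cost','mean_qaly','status','icer']]
      .to_string(index=False))
```

prints (seed 1):

```
MIs prevented : 3.23 M
QALYs gained  : 10.75 M
          strategy   mean_cost  mean_qaly      status         icer
             shape 7840.044086  15.367089   dominated          NaN
             texas 7404.709350  15.430797   dominated          NaN
        status_quo 7620.590674  15.458562   dominated          NaN
              atp3 6934.002440  15.561177   dominated          NaN
           jupiter 7847.402411  15.581875   dominated          NaN
            accaha 6647.897071  15.617792 on-frontier          NaN
treat_all_moderate 8062.797472  15.624362   dominated          NaN
    treat_all_high 7394.470547  15.687780 on-frontier 10667.083273
```

Treating all men with high-dose generic statins prevents ≈3.2M MIs versus
current practice and gains ≈10.8M discounted QALYs; it is the most
effective strategy and sits on the efficiency frontier at ≈$10,700 per
QALY gained versus the risk-based guideline — far below the $50,000/QALY
willingness-to-pay threshold. The same comparison from a shell:

```bash
chdprevent simulate --strategy treat_all_high --sex male -n 30000 --seed 1
chdprevent analyze frontier -n 30000 --seed 1 --out results/
chdprevent analyze psa --replicates 100 --psa-n 5000 --seed 1 --out results/
```

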