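# ifcea

Cost-effectiveness microsimulation of **iron-fortified infant cereals
(IFC)** against iron-deficiency anaemia in children aged 6 to <24
months, for health economists and nutrition-policy analysts who want the
whole chain — synthetic cohort, Markov disease projection, DALY
accounting, ICER/willingness-to-pay evaluation, sensitivity analysis —
as tested, scriptable Python.

## The model

A virtual cohort of children (default 100,000, expanded by Monte-Carlo
resampling from a 1,707-child survey-like base with configurable
marginals for age band, sex, wealth quintile, anaemia severity and IFC
consumption) is split into an IFC arm and a non-IFC arm. Anaemia
severity *s ∈ {none, mild, moderate, severe}* (WHO haemoglobin cut-offs
11/10/7 g/dL) evolves over 20 six-month cycles under a row-stochastic
transition matrix **P** per arm, built from per-cycle rates via
*p = 1 − e^(−rate·t)* and restricted to adjacent states. A scalar
recovery multiplier is bisected so the comparator arm's prevalence at
cycle 20 hits its target (default 0.36), and the IFC arm applies a
relative risk *rr* on worsening rates, bisected to its own target
(default 0.27).

Burden is YLD-only DALYs: per-day DALY = Σ_s occ[s]·dw[s] with GBD-2019
anaemia weights (0.004/0.052/0.149), accumulated over 3,650 days and
discounted at 3%/year after year 1. Cost-effectiveness is

ICER = (C_IFC − C_nonIFC) / (E_IFC − E_nonIFC),

with food costs 0.37 USD/day (both arms) + 0.17 USD/day (IFC arm) over
18 months and effects in disability days, classified against WHO-CHOICE
GDP-per-capita thresholds (6.6 USD/day), plus net monetary benefit
NMB = λ·ΔE − ΔC. One-way (tornado) and probabilistic sensitivity
analysis (gamma costs / beta weights and rates, 1,000 runs) feed a
cost-effectiveness acceptability curve.

## Worked example

```python
from ifcea import AnaemiaCEA

res = AnaemiaCEA.from_config({"seed": 42}).fit()
print(res.summary())
```

```
Cost-effectiveness of iron-fortified infant cereals (IFC)
============================================================
cohort: n=100000 (Hb 10.57 +/- 1.81 g/dL), mode=cohort_fractions
horizon: 20 cycles x 182.5 days = 3650 days

Calibration
  recovery multiplier: 1.5485 (end prevalence 0.3600)
  IFC worsening relative risk: 0.7070
  anaemia prevalence at t1 -> t20: IFC 0.531 -> 0.270; non-IFC 0.548 -> 0.360

Indicator                                   IFC         non-IFC
DALY per day (total days, 10 years)      0.0064 ( 23.4)   0.0088 ( 32.2)
Cost of food per day (total, 18 months)   0.540 ( 291.6)   0.370 ( 199.8) USD

disability days averted over horizon: 8.79 (discounted 7.60)
incremental cost: 91.80 USD
ICER: -10.448 USD per disability day [NE: more costly, more effective]
ICER per DALY: -3813.4 USD
WHO-CHOICE classification at 6.6 USD/day: cost-effective
net monetary benefit: -33.81 USD
population savings (4,058,000 children, 1.92 USD/day): 7.79 million USD
```

Reading the output: both arms start at the cohort's ~55% anaemia
prevalence; calibration drives the comparator to 36% and the IFC arm to
27% after 10 years. Fortification costs 91.80 USD more per child over
18 months and averts 8.8 disability days, so each day averted costs
about 10.4 USD — the negative sign only records that the intervention
sits in the "more costly, more effective" quadrant (days are a burden
measure, so the effect difference is negative). At a willingness to pay
of one daily GDP per capita the incremental cost is not yet offset
(negative NMB at λ = 6.6); against the 3× GDP WHO-CHOICE band the
intervention is cost-effective.

Sensitivity analysis and plots hang off the results object:

```python
tornado = res.one_way()            # ICER swing per parameter
psa     = res.run_psa(seed=42)     # 1,000 gamma/beta draws
curve   = res.ceac(psa)            # acceptability vs willingness-to-pay
res.plot_tornado(tornado); res.plot_ce_plane(psa); res.plot_ceac(curve)
```

The same pipeline is scriptable from the shell:

```bash
ifcea report  --seed 42                      # fitted summary to stdout
ifcea simulate --config my.yaml --out runs/  # cohort + trajectories + burden CSVs
ifcea cea --config my.yaml                   # CEA table and text report
ifcea oneway --config my.yaml --plots        # tornado CSV/PNG
ifcea psa --config my.yaml --n-runs 1000     # PSA samples, summary, CEAC
```

Every output directory gets a `run_metadata.json` (config digest, seed,
version) and the resolved config, so any run can be reproduced exactly.

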