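# Methods

`ifcea` evaluates whether adding iron-fortified infant cereals (IFC) to
home-based complementary feeding of children aged 6 to <24 months is a
cost-effective way to reduce iron-deficiency anaemia, using a calibrated
Markov state-transition model over a 10-year horizon. This note records
the model, its assumptions, the parameters that matter, and the design
choices made where published information under-determines the analysis.

## Synthetic cohort

No child-level survey microdata are redistributable, so the package
generates a synthetic cohort with the same structure: age band (6–<12,
12–<18, 18–<24 months), sex, household wealth quintile, haemoglobin
(Hb, g/dL), anaemia severity, and an IFC-consumption flag. Marginal
frequencies default to the published survey margins of 1,707 children
(41.30% no anaemia, 24.02% mild, 33.63% moderate, 1.05% severe; IFC
consumption 5.6% of boys, 4.3% of girls). Fields are sampled
independently — the survey table reports no significant associations
between them (all p > 0.13) — except Hb, which is drawn conditionally on
severity from a normal truncated to that severity's Hb interval
(half-open, lower-closed: mild = [10, 11) g/dL, moderate = [7, 10),
severe = below 7; no anaemia = 11 and above).

The per-state Hb means/SDs default to none 12.0±1.0, mild 10.5±0.5,
moderate 8.5±0.75, severe 6.0±0.5 g/dL. Mild and moderate sit at their
interval midpoints; the unbounded-above "none" interval and the severe
tail instead use values chosen to keep the overall cohort near the
survey's 10.56±1.60 g/dL (a soft check, not a constraint — the generated
mean is ≈10.5). The base cohort (default n = 1,707) is expanded to a
virtual cohort (default n = 100,000) by resampling with replacement, so
every joint frequency converges to the base frequency.

What the generator does **not** emulate: survey weights and clustering,
urban/rural geography, real correlations between wealth, feeding
practice and anaemia, seasonality, and measurement error in Hb. Passing
tests therefore demonstrate the correctness and calibration behaviour of
the pipeline under the stated marginals, not external validity for any
real population.

## Markov model

Four ordered states (none < mild < moderate < severe) evolve in 20
six-month cycles (cycle = 182.5 days, horizon = 3,650 days). By default
only adjacent-state transitions are allowed per cycle — the conservative
reading of severity moving one step at a time over six months — giving a
birth-death chain with three worsening and three recovery channels.
Probabilities come from per-cycle rates via p = 1 − exp(−rate·t), so an
intervention effect expressed as a relative risk (RR) multiplies rates,
not probabilities. Matrices are time-homogeneous: the IFC effect,
acquired during the ≤18-month exposure window, is carried as a
persistent arm-specific matrix over the whole horizon. There is no death
state (no anaemia-attributable mortality rates are available at these
ages in the source setting), and no age-dependence of transitions.

### Calibration

The underlying transition equations are not published, so the chain is
calibrated to the reported prevalence endpoints:

1. **Structural rates.** Worsening rates default to (0.15, 0.20, 0.01)
   per cycle and recovery-rate shape to (0.30, 0.30, 0.50). These were
   chosen once so that (a) the anaemic pool is moderate-dominant, as in
   the survey cross-section (moderate 33.6% > mild 24.0%), (b) the
   severe pool stays near its observed ~1% share, and (c) the non-IFC
   equilibrium prevalence lies near the mid-30s so the reported decline
   is reachable. They are config values, freely overridable.
2. **Recovery level.** A scalar multiplier on the recovery rates is
   solved by bisection (multiplier bracket narrowed to 1e-6, prevalence
   tolerance 1e-4) so the comparator arm's projected prevalence at cycle
   20 hits its target (default 0.36). End prevalence is monotone
   decreasing in the multiplier, so bisection is valid; an unreachable
   target raises an error reporting the bracket.
3. **Intervention effect.** The IFC arm's matrix is the comparator
   matrix with worsening rates scaled by an RR, itself bisected so the
   IFC arm's cycle-20 prevalence hits its target (default 0.27). With
   the defaults the calibrated RR is ≈0.71, inside the range implied by
   published fortification trials.

Baseline occupancy defaults to the **pooled** cohort state fractions for
both arms: the generator draws the IFC flag independently of baseline
state, so the arms share a baseline distribution by construction, and
the small IFC arm's own empirical fractions (≈5% of the cohort) are
dominated by sampling noise that can spuriously violate the expected
ordering of the arms. Per-arm empirical baselines
(`transitions.baseline_occupancy: per_arm`) and explicit start
prevalences (e.g. the reported 0.57/0.59) remain available. With a
common baseline and a worsening RR < 1, the IFC arm's prevalence is
pointwise below the comparator's at every cycle, which the tests assert.

Projection runs either as a deterministic cohort-fraction recursion
(occupancy·Mᵗ) or as an individual-level microsimulation in which each
child's state is sampled per cycle; children are independent chains, so
microsimulated occupancy is binomial around the deterministic
projection, and agreement within Monte-Carlo error at n = 100,000 is an
acceptance property.

## Disability burden

DALYs are years lived with disability only (YLL = 0; no mortality is
modelled). Each cycle contributes occupancy-weighted disability:
per-day DALY = Σ_s occupancy[s]·dw[s], with GBD-2019 anaemia disability
weights (mild 0.004, moderate 0.052, severe 0.149; configurable).
Disability days over the horizon sum per-cycle contributions × 182.5
days; "DALY per day" is the undiscounted total divided by 3,650.
Discounting is 3% per year applied after a 1-year grace period, with a
cycle's year = ceil(t·182.5/365); discounted totals are reported
alongside undiscounted ones.

A deliberate consequence of using the GBD-2019 weights: the model's own
10-year disability-day totals (≈24 vs ≈32 days at the default
calibration) are substantially below the published 77/99 days. No
occupancy path over these four states with these weights can average
0.027 DALY/day at prevalences ≤ 0.59, so the published totals imply a
different (unpublished) weighting. The published per-arm values are
therefore treated as *inputs* when reproducing the published identity
arithmetic (0.027 − 0.021 = 0.006 DALY/day; 99 − 77 = 22 days; ICER
(291 − 199.8)/(77 − 99) = −4.145), while the model's own totals are
reported under separate names. The identities hold exactly on
undiscounted days, which is why costs and the headline ICER are not
discounted; all food costs fall in years 1–2 in any case.

## Costs and cost-effectiveness

Per-day food costs: 0.37 USD home-based foods (both arms) + 0.17 USD
IFC increment (intervention arm), over an intervention window of
6/12/18 months (30-day months) depending on starting age; the headline
uses the 18-month maximum: 199.8 USD vs 291.6 USD per child.

The ICER divides incremental cost by incremental effect. The headline
effect unit is disability days (burden: lower is better), making the
denominator negative — "more costly, more effective", reported with its
cost-effectiveness-plane quadrant so it is never confused with
dominance; a DALY-denominated ICER is reported alongside. WHO-CHOICE
classification compares |ICER| against 1× and 3× the daily GDP per
capita (default 6.6 USD), using the absolute value because the negative
sign here encodes the direction of the effect units, not cost savings.
Net monetary benefit is wtp·ΔE − ΔC with ΔE = days averted. The
national savings figure multiplies the published 1.92 USD per disability
day saved by 4.058 million children; 1.92 is not derivable from the
other published inputs (91.2/22 ≈ 4.15) and is carried as a config
constant, not a computed quantity.

## Sensitivity analysis

**One-way:** each parameter in {home-food cost, IFC cost increment,
three disability weights, IFC relative risk, recovery multiplier} is
moved to its bounds (default ±20% relative) with all else at base, and
the deterministic pipeline re-run; results are tornado-ordered by swing.
Because home-food cost enters both arms identically it cancels from the
incremental cost and has zero swing — the IFC increment is structurally
the dominant cost parameter.

**Probabilistic:** gamma distributions for costs, beta for weights and
the two transition-rate parameters, parameterised by method of moments
from mean and 95% CI (SD = CI width / 3.92, normal quantiles). Rate
parameters centre on their calibrated values with ±20% relative CIs;
no re-calibration occurs inside the PSA. Default 1,000 runs over the
100,000-child cohort; each run re-projects the deterministic
cohort-fraction pipeline, so PSA spread reflects parameter uncertainty
rather than microsimulation noise (individual-mode draws would add
binomial noise without changing the expectation). Failed draws (e.g. a
draw making a matrix row infeasible) are recorded with reasons and
excluded from summaries. Median ICER and IQR are reported, optionally
stratified by sex or wealth quintile (strata differ through their
baseline occupancy). The CEAC counts draws with NMB ≥ 0 per WTP; it is
monotone non-decreasing whenever all effect gains are non-negative,
which holds structurally here (RR < 1 ⇒ days averted > 0) — with
mixed-sign gains no estimator of this form is monotone.

The published PSA scenario values (median −29.8/5.09/5.63 USD under
cost reductions; 80%/40% acceptability) depend on unpublished
distribution hyperparameters and an unstated WTP; they are treated as
qualitative scenario shapes, not reproduction targets.

## Numerical and degenerate-input conventions

- Probability vectors must sum to 1 within 1e-12 (specs) / 1e-9
  (matrices, occupancies); rows are validated on every construction.
- Bisection: 1e-6 on the solved scalar, 1e-4 on prevalence; brackets are
  expanded by doubling and reported on failure.
- A stationary target with zero worsening accepts a zero recovery rate.
- Hb sampling clips to just inside the open upper interval bound so
  categorisation is exact at boundaries.
- Equal arm effects make the ICER undefined: an error directs users to
  NMB, and PSA records such draws as failures.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; same config + seed gives
  byte-identical outputs end to end.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run the pipeline at a 2,000-child cohort, PSA
at 25–400 runs; full-scale checks (100,000-child expansion and
microsimulation, 1,000-run PSA) run in the acceptance properties and
script, where the whole pipeline completes in seconds.

## Known limitations

- Transition dynamics are calibrated to two prevalence endpoints, not
  estimated from longitudinal data (none exist for this population);
  within-anaemia severity dynamics are only weakly identified.
- Disability-day totals depend directly on the GBD weights; see above.
- No mortality, no comorbidity or other micronutrient burdens, no
  healthcare-utilisation or productivity costs, no survey weighting, no
  correlated PSA sampling, no EVPI.
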