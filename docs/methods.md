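# Methods

## Model structure

A cohort of 80-year-old patients with severe symptomatic aortic stenosis
at intermediate surgical risk receives either TAVI or SAVR at model start
and then moves monthly between three states: **no stroke**, **stroke**
(disabling/major stroke with long-term sequelae) and **death**
(absorbing). Stroke here is the only state-defining complication; the ten
other adverse events (rehospitalisation, MI, major vascular complication,
life-threatening/disabling bleeding, endocarditis, AKI, new permanent
pacemaker, TIA, atrial fibrillation, moderate-to-severe paravalvular
regurgitation) strike independently of health state, each at most once
per patient, and affect costs (and, in one scenario, utilities) but not
transitions. Within a cycle the order is: adverse events → stroke onset →
death. A patient dying in a cycle forfeits that cycle's utility and
follow-up costs but keeps AE costs already incurred that cycle.

The base-case horizon is 60 monthly cycles (the span of the five-year
trial evidence, avoiding extrapolation); a 20-year horizon is a scenario.
Costs and QALYs are discounted at 3%/year, factor $(1.03)^{-t/12}$ at
cycle $t$; the index episode charge is booked at model start
undiscounted. No half-cycle correction is applied by default (a config
flag adds one), consistent with default cycle-tree evaluation in common
decision-modelling software.

## From landmark probabilities to monthly transitions

Inputs are Kaplan–Meier landmark values at months 1, 12, 24 and 60 per
event and arm. Within a landmark interval of length $n$ the conditional
monthly probability is constant: $p = 1 - (S_k/S_{k-1})^{1/n}$. (The
conditional-probability form is used throughout; the alternative
orientation $1 - S(t-1)/S(t)$ produces negative values for any declining
survival curve and is treated as a typographical variant.)

Two refinements:

* **Late mortality bridging.** The five-year mortality landmarks were
  projected from two-year curves assuming a linear increase over time, so
  for all-cause mortality the model defaults to a *linear rise of
  cumulative probability* across intervals extending beyond month 24
  (`late_mortality_bridging: linear`). Both bridgings reproduce every
  landmark exactly; the choice moves only the within-interval shape, and
  it determines when cumulative TAVI mortality overtakes SAVR: cycle 45
  (3.75 years) under linear bridging, cycle 42 under constant-rate. The
  constant-rate alternative is a config switch.
* **Prevalence events.** The paravalvular-regurgitation rows are
  prevalences (they fall between 2 and 5 years); a cumulative incidence
  cannot fall. New incidence is generated only from the positive
  prevalence increments; falling prevalence produces no events and no
  cost refunds, since AE costs are one-time at incidence.

Beyond the last landmark (the 20-year scenario) the last interval's
constant-rate equivalent continues for every event; utilities and
follow-up costs continue at their final values.

## Stroke/no-stroke mortality split

Patients in the stroke state carry an elevated death hazard for 15 months
after onset (hazard ratios 8.5 → 1.16 by month 15; 1.0 afterwards, i.e.
no residual excess hazard — the model reads "revert to background
mortality" as reverting to the no-stroke hazard). The ratios index
*months since stroke onset*, not model time, so the cohort trace
stratifies stroke occupancy by duration (16 strata: months 1–15 and 16+)
and the microsimulation tracks each patient's onset cycle. Writing $M(t)$
for the cohort monthly mortality implied by the landmarks, $X_d$ for the
stroke-stratum shares among survivors and $RR_d$ for the duration-indexed
ratios, the no-stroke probability solves the mixture identity

$$M_{NS}(t) = \frac{M(t)}{\sum_d X_d RR_d + \left(1 - \sum_d X_d\right)},$$

and stratum $d$ dies with $\min(RR_d\,M_{NS}, 1)$. Because the split uses
the model's own mixture, recombined cohort mortality equals $M(t)$
exactly and the simulated cumulative mortality reproduces every landmark
(machine precision; the tests assert 1e-9). If capping at 1 ever bound
(it does not with the bundled inputs), the solver redistributes the
excess to preserve $M(t)$.

## Accrual rules

* **Costs (2020 US$; a ×1.32 S$ conversion is reporting-only).** Index
  episode 54,301 (TAVI) / 26,109 (SAVR) at start. One-time AE treatment
  cost per new incidence, in the incidence cycle. Annual cardiology
  follow-up 372 spread as 372/12 per alive patient-month; neurologist
  visits 243 quarterly in the stroke state, spread as 243/3 per
  stroke-state month. Expected AE incidence in cohort mode multiplies the
  alive fraction by a per-event event-free fraction (events assumed
  independent of each other and of state), matching the once-per-patient
  microsimulation rule in expectation.
* **QALYs.** Occupancy × utility/12 per cycle. Utilities interpolate
  linearly between the month-1, month-12 and month-24 trial values per
  arm; beyond month 24 both arms carry the last TAVI value (0.78). The
  base case adds no AE disutilities (the trial utilities already reflect
  AE burden). Scenario 4 applies a 0.161 utility decrement per cycle in
  the stroke state and one-off decrements at each non-stroke AE
  incidence; only the stroke value is published, so the bundled one-off
  set is a synthetic uniform stand-in (0.1 utility for one month =
  0.00833 QALYs per event), chosen a priori as a typical transient-AE
  loss.

## Sensitivity and scenario analyses

* **OWSA** varies one parameter at a time to its 95% CI bounds where
  reported (AE costs, utilities), else ±20% (index episode and follow-up
  costs), with the discount rate swept 0–5%; evaluation is deterministic
  (cohort) so the tornado isolates parameter effects from first-order
  noise. Setting a parameter to its base value reproduces the base ICER
  exactly (asserted). Re-basing the pooled post-24-month utility follows
  any change to the TAVI month-24 node.
* **PSA** (5,000 second-order draws, seeded): first-milestone event
  probabilities ~ beta, utilities ~ beta, AE costs ~ gamma, all by method
  of moments; parameters are drawn independently (no correlation
  structure is reported). Utility spreads come from the reported CIs
  (sd = width/3.92), cost spreads from the reported SDs; first-month
  probabilities have no reported CI, so sd = 0.2·mean/1.96, the ±20%
  convention read as a 95% interval. Draws violating cumulative
  monotonicity are redrawn (bounded retries); infeasible beta moments
  raise rather than clamp. Each draw is evaluated in cohort mode (exact
  expectation), so the CEAC reflects parameter uncertainty only. The
  headline mean ICER is the ratio of mean increments — robust to
  near-zero ΔQALY draws; the unstable mean of per-draw ICERs is reported
  alongside.
* **Scenarios.** (1) PARTNER S3i and (2) SURTAVI clinical inputs are
  *synthetic reconstructions*: the published supplementary input tables
  are not among this package's sources, so the bundled files encode the
  values the main text states (S3i one-year mortality 6.5%/12.2%
  extrapolated linearly to 26.8%/41.3% at five years; SURTAVI two-year
  data with both arms projected beyond month 24 at the SAVR second-year
  rate and the TAVI monthly death risk overtaking SAVR from about month
  11), with remaining events carried over from the base case. (3) extends
  the horizon to 240 cycles under the extension rule above. (4) switches
  on the AE disutilities.

## Synthetic-data generator

`tavicea.synthetic` builds parameter sets from known piecewise-constant
monthly hazards: milestone tables are exact closed-form cumulative
incidences, or, with noise on, empirical CDFs of event times simulated
for a finite cohort (binomial sampling at each landmark; no censoring
process, mirroring how digitised landmark values behave). Synthetic specs
default to constant-rate bridging — the exact inverse of rate-based
generation — so recovery checks hold to 1e-6. The generator emulates the
*structure* of the trial inputs (landmark grid, two arms, constant costs
and utilities), not their clinical content: passing recovery tests shows
the conversion/evaluation machinery is exact, not that real KM curves are
piecewise-exponential between landmarks.

## Numerical choices and problem sizes

Probabilities live in [0, 1] by construction; validation enumerates every
violated invariant rather than fixing silently. The microsimulation is
vectorised over patients with a fixed per-cycle draw order (one uniform
per AE, one for stroke, one for death) so identical seeds give identical
results; arm-level seeds are spawned from the analysis seed. Default
sizes follow the source analysis (10,000 first-order iterations, 5,000
second-order draws, seed 1); the test suite uses the deterministic cohort
mode wherever exactness matters and 10²–10⁵ patients for convergence
checks. A full 5,000-draw PSA runs in ~20 s on one core.

## Known limitations

* The published analysis consumed monthly digitised KM curves for
  mortality and stroke; only the four landmark values are printed, so the
  within-interval shape here is modelled, not observed. The per-arm
  totals land within a few percent of the published ones, but ratio
  quantities (ICER, INB) are more sensitive — `docs/validation.md`
  itemises the residuals.
* Scenario 1/2 inputs and the non-stroke disutilities are reconstructions
  (see above), so those scenario results validate the machinery and the
  stated qualitative claims more than the exact published figures.
* AE risks are arm- and time-specific but state-independent, each event
  can occur once per patient, and AE-mortality interactions are assumed
  captured in all-cause mortality — all inherited simplifications of the
  source model.
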