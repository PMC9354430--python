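# tavicea

A cost-effectiveness model of **transcatheter aortic valve implantation
(TAVI)** versus **surgical aortic valve replacement (SAVR)** for patients
with severe symptomatic aortic stenosis at *intermediate* surgical risk
(STS score 4–8%), from a healthcare-system perspective with Singapore cost
inputs (2020 US$).

It is aimed at health-economics analysts who want a transparent,
scriptable re-implementation of a three-state Markov decision model whose
every input is a published number: Kaplan–Meier landmark probabilities for
all-cause mortality, disabling stroke and ten further adverse events
(PARTNER 2A five-year data in the base case), stroke-vs-no-stroke
mortality hazard ratios, episode/AE treatment charges, and EQ-5D
utilities.

## The model

Three health states — *no stroke*, *stroke* (disabling, with long-term
sequelae) and *death* — evolve in monthly cycles over a 5-year horizon
(20 years in a scenario). Landmark probabilities $C(t_k)$ become
conditional monthly probabilities $p$ with

$$(1-p)^{n} = S(t_k)/S(t_{k-1}), \qquad S = 1 - C,$$

i.e. a constant monthly rate within each landmark interval (all-cause
mortality from 2 to 5 years instead rises linearly in cumulative
probability, matching how the five-year mortality points were projected).
Cohort mortality $M$ is split by stroke status through the mixture
identity

$$M_{NS} = \frac{M}{X\,RR_S + (1 - X)}, \qquad M_S = RR_S\, M_{NS},$$

where $X$ is the stroke-state share of survivors and $RR_S$ the hazard
ratio for the current month since stroke onset (8.5 in the onset month,
declining to 1.16 by month 15, 1 afterwards). Costs accrue as the index
episode charge, one-time AE treatment costs on incidence, an annual
cardiology visit, and a quarterly neurologist visit in the stroke state;
QALYs accrue as occupancy × utility / 12, with utilities interpolated
linearly between months 1, 12 and 24 and pooled to the last TAVI value
afterwards. Costs and QALYs are discounted at 3%/year. Evaluation is
either a deterministic cohort trace (stroke occupancy stratified by months
since onset) or a seeded first-order microsimulation; the cohort trace is
the exact expectation of the microsimulation.

On top sit the standard decision-analytic layers: ICER and dominance
labelling, incremental net monetary benefit (INB = WTP·ΔQALY − ΔC),
one-way sensitivity analysis with tornado ordering (95% CI bounds, else
±20%; discount 0–5%), probabilistic sensitivity analysis (beta-distributed
first-month probabilities and utilities, gamma-distributed AE costs, by
method of moments) with a cost-effectiveness acceptability curve, and four
scenario analyses (PARTNER S3i inputs, SURTAVI inputs, 20-year horizon,
AE disutilities).

## Worked example

```sh
$ tavicea run base --out out/
flags in effect: {'late_mortality_bridging': 'linear', 'half_cycle_correction': False,
'apply_ae_disutilities': False, 'annual_discount': 0.03, 'horizon_months': 60}
TAVI US$67,219 / 2.90 QALYs; SAVR US$39,794 / 2.82 QALYs; dC US$27,425,
dQALY 0.074; ICER US$368,621/QALY [icer]; INB US$-24,889 at WTP US$34,091
results written to out
```

Reading: a TAVI patient costs US$67,219 discounted over five years
(US$54,301 index episode + US$11,384 expected AE treatment + follow-up)
against US$39,794 for SAVR, and gains 0.074 discounted QALYs — TAVI's
early survival and quality-of-life advantage erodes as its cumulative
mortality overtakes SAVR at 3.75 years. The resulting ICER of roughly
US$369,000 per QALY, and the negative net benefit at a WTP of US$34,091
(S$45,000), say TAVI is unlikely to be cost-effective in this group. The
same library calls are available in Python:

```python
from tavicea import builtin_parameter_set
from tavicea.analyses import base_case, psa

result = base_case(builtin_parameter_set("partner2a_base"))
print(round(result.icer))          # 368621
print(round(result.delta_qaly, 3)) # 0.074
```

`tavicea run owsa|psa|scenario1..4` produce the tornado table/figure, PSA
draws with the CEAC, and the scenario comparisons; `tavicea validate`
checks a YAML parameter file and can export a flat CSV audit table;
`tavicea make-synthetic` writes a parameter set generated from known
hazards for testing. See `docs/methods.md` for modelling details and
`docs/validation.md` for the comparison against the published results.

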