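# Base-case parameter set: PARTNER 2A transfemoral intention-to-treat
# clinical milestones (KM estimates at 30 days / 1 y / 2 y / 5 y),
# Singapore MOH Casemix episode charges (2020 US$), EQ-5D utilities.
# Probabilities are fractions; PAR rows are prevalences (they fall from
# 2 y to 5 y), all other rows cumulative incidences.
name: partner2a_base
description: >
  Base case: five-year PARTNER 2A clinical evidence, 5-year horizon,
  monthly cycles, 3% annual discounting, 10,000-iteration microsimulation.
settings:
  horizon_months: 60
  cycle_length_months: 1
  annual_discount: 0.03
  wtp: 34091.0
  n_microsim: 10000
  n_psa: 5000
  seed: 1
  apply_ae_disutilities: false
  late_mortality_bridging: linear
  half_cycle_correction: false
  usd_to_sgd: 1.32
events:
  all_cause_mortality:
    kind: cumulative_incidence
    tavi: [[1, 0.03], [12, 0.10], [24, 0.142], [60, 0.427]]
    savr: [[1, 0.041], [12, 0.123], [24, 0.172], [60, 0.405]]
  disabling_stroke:
    kind: cumulative_incidence
    tavi: [[1, 0.023], [12, 0.043], [24, 0.053], [60, 0.087]]
    savr: [[1, 0.042], [12, 0.060], [24, 0.067], [60, 0.083]]
  rehospitalisation:
    kind: cumulative_incidence
    tavi: [[1, 0.055], [12, 0.131], [24, 0.184], [60, 0.32]]
    savr: [[1, 0.065], [12, 0.148], [24, 0.171], [60, 0.241]]
  mi:
    kind: cumulative_incidence
    tavi: [[1, 0.006], [12, 0.019], [24, 0.03], [60, 0.094]]
    savr: [[1, 0.018], [12, 0.032], [24, 0.042], [60, 0.081]]
  major_vascular:
    kind: cumulative_incidence
    tavi: [[1, 0.085], [12, 0.088], [24, 0.09], [60, 0.096]]
    savr: [[1, 0.039], [12, 0.043], [24, 0.045], [60, 0.051]]
  bleeding:
    kind: cumulative_incidence
    tavi: [[1, 0.067], [12, 0.111], [24, 0.136], [60, 0.211]]
    savr: [[1, 0.414], [12, 0.434], [24, 0.447], [60, 0.486]]
  endocarditis:
    kind: cumulative_incidence
    tavi: [[1, 0.0], [12, 0.008], [24, 0.015], [60, 0.037]]
    savr: [[1, 0.0], [12, 0.009], [24, 0.009], [60, 0.019]]
  aki:
    kind: cumulative_incidence
    tavi: [[1, 0.005], [12, 0.022], [24, 0.025], [60, 0.034]]
    savr: [[1, 0.03], [12, 0.052], [24, 0.064], [60, 0.10]]
  new_ppi:
    kind: cumulative_incidence
    tavi: [[1, 0.081], [12, 0.096], [24, 0.114], [60, 0.151]]
    savr: [[1, 0.071], [12, 0.095], [24, 0.108], [60, 0.135]]
  tia:
    kind: cumulative_incidence
    tavi: [[1, 0.009], [12, 0.026], [24, 0.038], [60, 0.058]]
    savr: [[1, 0.003], [12, 0.018], [24, 0.023], [60, 0.043]]
  af:
    kind: cumulative_incidence
    tavi: [[1, 0.049], [12, 0.059], [24, 0.074], [60, 0.117]]
    savr: [[1, 0.267], [12, 0.276], [24, 0.278], [60, 0.307]]
  par:
    kind: prevalence
    tavi: [[1, 0.0375], [12, 0.0375], [24, 0.0827], [60, 0.0644]]
    savr: [[1, 0.0049], [12, 0.0049], [24, 0.0057], [60, 0.0034]]
hazard_ratios:
  # mortality HR, stroke vs no-stroke, by month since stroke onset (1..15);
  # no excess hazard beyond 15 months.
  by_post_stroke_month: [8.5, 4.72, 3.58, 2.97, 2.63, 2.21, 2.15, 1.83,
                         1.86, 1.5, 1.51, 1.42, 1.22, 1.19, 1.16]
  after: 1.0
costs:
  index_episode:
    tavi: 54301.0
    savr: 26109.0
  followup_annual: 372.0       # one cardiologist visit per year, all alive patients
  neurologist_visit: 243.0     # every three months, stroke state only
  ae:
    disabling_stroke: {mean: 14243.0, sd: 11914.0, ci: [4252.0, 47508.0]}
    rehospitalisation: {mean: 6120.0, sd: 9280.0, ci: [667.0, 26476.0]}
    mi: {mean: 13736.0, sd: 13143.0, ci: [1436.0, 44309.0]}
    major_vascular: {mean: 13773.0, sd: 13858.0, ci: [3486.0, 54403.0]}
    bleeding: {mean: 8652.0, sd: 7524.0, ci: [2408.0, 30786.0]}
    endocarditis: {mean: 26952.0, sd: 29945.0, ci: [1813.0, 114305.0]}
    aki: {mean: 6203.0, sd: 8445.0, ci: [711.0, 28414.0]}
    new_ppi: {mean: 13384.0, sd: 8805.0, ci: [5856.0, 34942.0]}
    tia: {mean: 2842.0, sd: 2213.0, ci: [749.0, 7819.0]}
    af: {mean: 5152.0, sd: 8535.0, ci: [597.0, 25330.0]}
    par: {mean: 22231.0, sd: 20436.0, ci: [831.0, 69572.0]}
utilities:
  tavi:
    nodes:
      1:  {mean: 0.81, ci: [0.79, 0.82]}
      12: {mean: 0.79, ci: [0.78, 0.81]}
      24: {mean: 0.78, ci: [0.76, 0.79]}
    pooled_after_month: 24
    pooled_value: 0.78         # last TAVI value, applied to both arms
  savr:
    nodes:
      1:  {mean: 0.73, ci: [0.71, 0.74]}
      12: {mean: 0.80, ci: [0.78, 0.81]}
      24: {mean: 0.77, ci: [0.75, 0.79]}
    pooled_after_month: 24
    pooled_value: 0.78
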