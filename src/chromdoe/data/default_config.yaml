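# Default end-to-end workflow configuration: the gradient-optimisation study
# conditions and the quantitative-robustness screening layout.
seed: 20230914
factors:
  - {name: methanol_initial, center: 37.5, half_range: 2.5, unit: "% v/v"}
  - {name: methanol_final,   center: 80.0, half_range: 5.0, unit: "% v/v"}
  - {name: gradient_duration, center: 17.5, half_range: 2.5, unit: "min"}
models:
  t_e_imp_x: quadratic
  t_b_imp_III: quadratic
  t_imp_V: quadratic
  W_USP: linear
  t_range: quadratic
cmas:
  - {name: t_imp_V, response: t_imp_V, comparator: "<", threshold: 15.5}
  - {name: t_range, response: t_range, comparator: "<", threshold: 12.0}
  - {name: S, kind: difference, minuend: t_b_imp_III, subtrahend: t_e_imp_x, comparator: ">=", threshold: 0.0}
  - {name: W_USP, response: W_USP, comparator: "<=", threshold: 0.235}
grid:
  methanol_initial: [35.0, 0.25, 40.0]
  methanol_final: [75.0, 0.5, 85.0]
  gradient_duration: [15.0, 0.5, 20.0]
monte_carlo:
  n_iterations: 5000
  perturbation: uniform_halfwidth_se
pi_min: 0.8
working_point: [38.5, 77.5, 16.25]
slice:
  fixed_factor: gradient_duration
  fixed_value: 16.25
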