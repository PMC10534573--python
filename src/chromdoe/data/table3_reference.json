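{
  "description": "Published coded-factor model coefficients and determination coefficients for the five critical responses of the gradient study (reference values for comparison and as synthetic ground truth).",
  "term_order": ["b0", "b1", "b2", "b3", "b12", "b13", "b23", "b11", "b22", "b33"],
  "coefficients": {
    "t_imp_V":     {"b0": 15.554, "b1": -0.511, "b2": -1.076, "b3": 1.321, "b12": 0.029, "b13": -0.087, "b23": -0.090, "b11": -0.050, "b22": 0.094, "b33": 0.006},
    "t_e_imp_x":   {"b0": 13.443, "b1": -0.598, "b2": -0.878, "b3": 1.113, "b12": 0.068, "b13": -0.108, "b23": -0.073, "b11": -0.055, "b22": 0.065, "b33": 0.045},
    "t_b_imp_III": {"b0": 13.458, "b1": -0.593, "b2": -0.890, "b3": 1.115, "b12": 0.057, "b13": -0.108, "b23": -0.073, "b11": -0.053, "b22": 0.072, "b33": 0.028},
    "W_USP":       {"b0": 0.2289, "b1": 0.0041, "b2": -0.0132, "b3": 0.0152},
    "t_range":     {"b0": 11.272, "b1": -0.042, "b2": -1.067, "b3": 1.306, "b12": 0.012, "b13": -0.072, "b23": -0.092, "b11": -0.080, "b22": 0.095, "b33": -0.011}
  },
  "rsquared":      {"t_imp_V": 0.9998, "t_e_imp_x": 0.9993, "t_b_imp_III": 0.9994, "W_USP": 0.9838, "t_range": 0.9999},
  "rsquared_adj":  {"t_imp_V": 0.9996, "t_e_imp_x": 0.9982, "t_b_imp_III": 0.9986, "W_USP": 0.9797, "t_range": 0.9996},
  "rsquared_pred": {"t_imp_V": 0.9995, "t_e_imp_x": 0.9984, "t_b_imp_III": 0.9977, "W_USP": 0.9711, "t_range": 0.9989}
}
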