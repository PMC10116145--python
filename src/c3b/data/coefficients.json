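{
  "schema_version": 1,
  "coefficient_set_id": "c3b-published-norms-v1",
  "models": [
    {
      "test_id": "PST",
      "intercept": 65.2217,
      "beta_age": -0.4591,
      "beta_nonlinear_age": -0.0053,
      "beta_education": 0.7999,
      "beta_sex": -2.2132,
      "beta_race": -4.0893,
      "rmse": 8.958,
      "nonlinear_basis": "quadratic_centered",
      "age_constant": 50.26714,
      "adjusted_r2": 0.4963
    },
    {
      "test_id": "VMT",
      "intercept": 58.8785,
      "beta_age": -0.3118,
      "beta_nonlinear_age": -0.0329,
      "beta_education": 0.7152,
      "beta_sex": null,
      "beta_race": -5.6555,
      "rmse": 12.879,
      "nonlinear_basis": "knot_spline",
      "age_constant": 71.0,
      "adjusted_r2": 0.224
    }
  ]
}
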