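{
  "n_families": 169,
  "frac_pg_families_two_pg": 0.16304347826086957,
  "base_logit": {
    "VGD1": -0.8472978603872034,
    "VGD2": -0.8472978603872034,
    "TSGD": -0.6632942174102642,
    "SSGD": 0.9946025731038356
  },
  "beta_pg": 0.0,
  "beta_category": {},
  "gamma_carryover": 0.0,
  "salmonid_fraction": 1.0,
  "interaction_model": {
    "mean_multigenic": 5.5,
    "mean_monogenic": 2.2,
    "dispersion": 2.0
  },
  "seed": 20180329
}
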