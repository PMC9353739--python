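# Packaged base-case inputs for the three-state Markov cost-utility model of
# first-line camrelizumab + pemetrexed/carboplatin vs pemetrexed/carboplatin
# in advanced nonsquamous NSCLC (Chinese health-care system perspective).
#
# All monetary values are USD (converted at the 2020 average exchange rate of
# 6.8974 CNY/USD by the original analysts; recorded here for provenance only).
# Weibull scale parameters are on the model-cycle time scale (21-day cycles).

settings:
  cycle_length_days: 21
  horizon_cycles: 174           # ceil(10 * 365.25 / 21): 10-year horizon
  annual_discount_rate: 0.05
  background_annual_mortality: 0.0071   # annual probability; approximates China's 2020 crude death rate
  wtp_per_qaly: 31510.57        # 3x 2020 Chinese per-capita GDP (10,503.52 USD)
  psa_draws: 1000
  cny_per_usd_2020: 6.8974      # provenance constant, not used in computation

# Fitted Weibull survival parameters, S(t) = exp(-scale * t^shape), t in cycles.
weibull:
  combo:
    PFS: {scale: 0.021350, shape: 1.210605}
    OS:  {scale: 0.006578, shape: 1.263333}
  chemo:
    PFS: {scale: 0.057642, shape: 1.019433}
    OS:  {scale: 0.010970, shape: 1.216254}

structure:
  induction_cycles: 4           # lower limit of the 4-6 cycle induction course
  camrelizumab_max_cycles: 34   # maximum camrelizumab exposure (combo arm)
  disease_mgmt_breakpoint_cycle: 18

# Per-cycle costs (USD), utilities, and the discount-rate row with their
# low/high ranges and sampling families for sensitivity analysis.
# direction: downward_only marks the negotiated camrelizumab price, which has
# no room to rise; its one-way range is [low, base].
parameters:
  - {name: cost_camrelizumab,          base: 424.51, low: 318.38, high: 424.51, family: gamma, direction: downward_only}
  - {name: cost_pemetrexed,            base: 393.99, low: 187.78, high: 402.11, family: gamma}
  - {name: cost_carboplatin,           base: 11.96,  low: 3.84,   high: 22.91,  family: gamma}
  - {name: cost_pretreatment,          base: 1.52,   low: 1.14,   high: 1.89,   family: gamma}
  - {name: cost_second_line_combo_arm, base: 392.61, low: 294.46, high: 490.76, family: gamma}
  - {name: cost_second_line_chemo_arm, base: 698.77, low: 524.08, high: 873.46, family: gamma}
  - {name: cost_admin_combo_le4,       base: 72.54,  low: 54.40,  high: 90.67,  family: gamma}
  - {name: cost_admin_combo_5_34,      base: 66.27,  low: 49.70,  high: 82.84,  family: gamma}
  - {name: cost_admin_combo_gt34,      base: 65.58,  low: 49.19,  high: 81.98,  family: gamma}
  - {name: cost_admin_chemo_le4,       base: 71.85,  low: 53.89,  high: 89.82,  family: gamma}
  - {name: cost_admin_chemo_gt4,       base: 56.36,  low: 42.27,  high: 70.45,  family: gamma}
  - {name: cost_disease_mgmt_first18,  base: 60.64,  low: 45.48,  high: 75.80,  family: gamma}
  - {name: cost_disease_mgmt_after18,  base: 48.68,  low: 36.51,  high: 60.85,  family: gamma}
  - {name: cost_ae_combo,              base: 120.06, low: 90.05,  high: 150.08, family: gamma}
  - {name: cost_ae_chemo,              base: 80.32,  low: 60.24,  high: 100.40, family: gamma}
  - {name: utility_pfs,                base: 0.804,  low: 0.536,  high: 0.883,  family: beta}
  - {name: utility_pd,                 base: 0.321,  low: 0.05,   high: 0.473,  family: beta}
  - {name: discount_rate,              base: 0.05,   low: 0.0,    high: 0.08,   family: fixed}
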