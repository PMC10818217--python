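# Default configuration: base-case parameter landscape of the decision model.
# All monetary values are 2022 euros; cycles are annual.
parameters:
  diagnostic_yield: {soc: 0.43, wes: 0.58, wgs: 0.64}
  p_change: {soc: 0.06, wes: 0.17, wgs: 0.27}
  # annual pathway "first contact, access and continuity of care" costs;
  # reported as a component, excluded from the base-case totals (see docs)
  care_cost: {soc: 29870.0, wes: 61704.0, wgs: 79170.0}
  test_cost: {soc: 450.0, wes: 1800.0, wgs: 3700.0}
  # one-off cost of a change in clinical management after diagnosis
  change_cost: {soc: 4241.0, wes: 9611.0, wgs: 15785.0}
  post_test_dx: 92.0       # annual, after a WES/WGS test, with diagnosis
  post_test_undx: 162.0    # annual, after a WES/WGS test, without diagnosis
  odyssey_cost: 2375.0     # annual, while in the diagnostic odyssey
  discount_rate: 0.03
  n_cycles: 60
  cohort_size: 1.0
  second_line_delay: 1
  post_soc_odyssey_years: 1
  include_change_costs: false
  include_care_costs: false
cohort:
  # hospital cohorts used to estimate diagnostic yields (conjugate beta update)
  n_tested: {soc: 300, wes: 480, wgs: 90}
  n_diagnosed: {soc: 129, wes: 278, wgs: 58}
priors:
  cost_ci_fraction: 0.2        # 95% limits at base*(1 ± fraction) for log-normal costs
  change_cost_half_width: 0.5  # uniform half-width fraction for change costs
  p_change_ess: 100            # effective sample size for management-change betas
  cost_ci_overrides: {}        # e.g. {test_cost_wgs: [2960.0, 4440.0]}
run:
  wtp_min: 0
  wtp_max: 50000
  wtp_step: 100
  n_draws: 100000
  n_chains: 4
  seed: 0
  eur_usd: 1.0875
  threshold_band: [30000, 50000]
  evpi_population: 10000     # annual affected population for population EVPI
  evpi_horizon_years: 10
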