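behavior:
  base_harvest_fraction: 0.9
  byproduct_sell_threshold: 0.25
  contract_horizon: 6
  cost_product_mult:
    energy: 0.6
    industrial: 0.7
    sawlogs: 1.0
  framework_years_max: 15
  framework_years_min: 5
  harvest_cost_base: 48.0
  harvest_cost_slope: 0.6
  harvest_elasticity_private: 0.6
  harvest_elasticity_public: 0.3
  heating_months:
  - 0
  - 1
  - 2
  - 3
  - 9
  - 10
  - 11
  max_initiations: 3
  max_initiations_large: 250
  month_room_factor: 1.3
  own_consumption:
    energy: 0.6
    industrial: 0.05
    sawlogs: 0.1
  phonebook_size: 10
  plan_horizon: 3
  reservation:
    energy: 0.55
    industrial: 0.25
    sawlogs: 0.42
  reservation_premium: 0.1
  reservation_release_month: 9
  reservation_unlock: 0.95
  season_months:
  - 0
  - 1
  - 2
  - 8
  - 9
  - 10
  - 11
  split_elasticity_private: 1.0
  split_elasticity_public: 0.5
  terrain_max: 1.3
  terrain_min: 0.8
  transport_cost_rate: 0.35
  trust_amount_floor: 0.15
decision:
  beta0:
    bundler_buy: 0.1
    bundler_sell: 0.1
    energy_buy: 0.4
    exporter_buy: 0.0
    importer_sell: 0.0
    industrial_buy: 0.4
    sawmill_buy: 0.5
    sawmill_sell: 0.4
    supplier_sell: 3.3
    trader_buy: 0.35
    trader_sell: 0.1
  epsilon_scale: 0.0
  heterogeneity_cv: 0.08
  part_worths:
    bundler_buy:
      margin: 2.0
    bundler_sell:
      margin: 2.0
    energy_buy:
      price: 1.5
      trust: 0.8
      urgency: 1.5
    exporter_buy:
      price: 4.0
    importer_sell:
      price: 4.0
    industrial_buy:
      price: 1.5
      trust: 0.8
      urgency: 1.5
    sawmill_buy:
      order_size: 0.3
      price: 2.0
      trust: 0.8
      urgency: 1.5
    sawmill_sell:
      price: 2.0
      stock_utilization: 1.0
      trust: 0.5
    supplier_sell:
      amount_available: 1.0
      amount_in_demand: 0.5
      margin: 3.0
      trust: 1.5
    trader_buy:
      price: 2.0
      trust: 0.5
    trader_sell:
      price: 2.0
      trust: 0.5
negotiation:
  adapt_fraction: 1.05
  anchor_ema: 0.01
  buy_discount: 0.1
  max_counter_ratio: 1.6
  price_ema: 0.3
  price_spread: 0.03
  urgency_wtp: 0.4
population:
  bundler:
    affiliation_radius_km: 25.0
    count_inner: 8
    count_outer: 15
    min_margin: 0.05
    monthly_volume: 600.0
  energy:
    count_inner: 50
    count_outer: 50
    demand_hard: 225.0
    demand_soft: 900.0
    stock_months: 1.0
  exporter:
    annual_increase: 20000.0
    count_inner: 6
    count_outer: 6
    initial_volume: 25000.0
    spread: 0.0
    transport_factor: 0.4
  importer:
    annual_increase: 3000.0
    count_inner: 6
    count_outer: 6
    initial_volume: 5000.0
    spread: 0.25
    transport_factor: 0.6
  industrial:
    count_inner: 1
    count_outer: 2
    demand_hard: 1200.0
    demand_soft: 4800.0
    stock_months: 2.0
  private:
    count_inner: 85
    count_outer: 85
    cv_supply: 0.6
    max_supply: 400.0
    mean_supply: 100.0
    min_supply: 10.0
    soft_share: 0.6
    splits_hard:
    - 0.01
    - 0.96
    - 0.03
    splits_soft:
    - 0.81
    - 0.15
    - 0.04
  public:
    count_inner: 85
    count_outer: 85
    cv_supply: 0.6
    max_supply: 12000.0
    mean_supply: 3500.0
    min_supply: 500.0
    soft_share: 0.97
    splits_hard:
    - 0.02
    - 0.95
    - 0.03
    splits_soft:
    - 0.81
    - 0.13
    - 0.06
  sawmill:
    byproduct_energy: 0.2
    byproduct_industrial: 0.15
    count_inner: 25
    count_outer: 25
    cv_capacity: 0.55
    hardwood_demand: 180.0
    hardwood_mills: 3
    max_capacity: 8000.0
    mean_capacity: 2300.0
    min_capacity: 800.0
    stock_months: 2.0
  trader:
    affiliation_radius_km: 25.0
    count_inner: 12
    count_outer: 12
    min_margin: 0.05
    monthly_volume: 600.0
prices:
  ar1_rho: 0.95
  ar1_sigma: 0.01
  fx_level: 1.0
  fx_rho: 0.98
  fx_sigma: 0.005
  levels:
    energy_hard: 60.0
    energy_soft: 60.0
    industrial_hard: 50.0
    industrial_soft: 55.0
    sawlogs_hard: 85.0
    sawlogs_soft: 90.0
  shocks: []
  trend: 0.0
region:
  detour_factor: 1.4
  inner_height_km: 60.0
  inner_width_km: 90.0
  international_border_fraction: 0.6666666666666666
  n_border_segments: 12
  outer_belt_km: 30.0
simulation:
  lcm_per_m3: 2.5
  settle_months: 36
  start_year: 2001
  years: 20
trust:
  exporter_initial: 0.9
  failure_step: 0.018
  floor_weight: 0.05
  initial: 0.5
  new_contact: 0.2
  regular_threshold: 0.7
  success_step: 0.018
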