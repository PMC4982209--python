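# Illustrative unit-cost table, 2012 GBP. Every figure is a replaceable
# configuration value: the ward-day rate (297) is anchored to the published
# post-ICU daily cost quartile; the critical-care day rates are tiered by
# the number of organ systems supported, mirroring how the National
# Schedule of Reference Costs tiers critical-care days; the remaining
# values are round representative magnitudes, not sourced prices.
base_year: 2012
cost_per_organ_day:
  0: 870.0
  1: 1213.0
  2: 1454.0
  3: 1686.0
  4: 1907.0
  5: 2132.0
  6: 2357.0
xray_cost: 25.0
chest_drain_cost: 150.0
rrt_cost: 300.0
drug_costs:
  abx: 20.0
  sedative: 10.0
  relaxant: 15.0
vent_machine_price: 18250.0
vent_machine_life_years: 5.0
vent_annual_maintenance: 365.0
vent_circuit_cost: 50.0
vent_utilisation_days_per_year: 365.0
stepdown_cost_per_day:
  ward: 297.0
  hdu: 741.0
  icu: 1476.0
transfer_cost: 450.0
sae_costs:
  pneumothorax: 500.0
  reintubation: 800.0
  other: 350.0
visit_costs:
  gp: 45.0
  outpatient: 111.0
  community: 38.0
inpatient_cost_per_day: 300.0
aids_costs:
  wheelchair: 150.0
  walking_frame: 60.0
  commode: 80.0
  grab_rail: 30.0
  other: 60.0
petrol_rate: 0.45
hchs_index:
  2010: 265.7
  2011: 270.3
  2012: 277.4
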