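schema: greenwallcba/scenario-v1
name: demo-3m-low-amenity
area_m2: 58.0
costs:
  invest_unit_cost: 500.0
  invest_lifetime: 10
  maintenance_unit_cost: 25.0
  cost_year: 2011
discount:
  rate: 0.03
  horizon: 40
  timing: start-of-year
project_year: 2011
noise_valuation:
  unit_price: 10.095
  price_year: 2002
  validity_cap: 71.0
  cutoff: 45.0
  quiet_side_factor: 0.3
exposures:
  - side: quiet
    level_before: 56.3
    level_after: 51.8
    persons: 115.0
amenity:
  unit_value: 0.6
  value_year: 2010
  roster:
    resident_persons: 115.0
    external_persons: 3.0
mc:
  draws: 10000
  seed: 0
  band: 0.90
  lower_truncation: 0.01
  perturbations:
    amenity_value: 0.50
    noise_effect: 0.30
    investment_cost: 0.30
    maintenance_cost: 0.30
    beneficiaries: 0.15
notes:
  - >-
    Amenity beneficiary total of 118 persons is back-derived from the
    published line item; 49 dwellings at 2.4 persons/household would give
    117.6 persons (within 1%).
  - >-
    Low-scenario amenity unit value is 0.6 EUR (2010), calibrated so the
    amenity line item equals exactly one quarter of the high-scenario
    value as published; the stated 0.5 EUR/person figure would give about
    0.21x instead.
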