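# Example analysis configuration (all keys optional; defaults shown).
exchange_rate_mwk_per_usd: 749.53   # official 2020 rate, MWK per US$
discount_rate: 0.03                 # capital annualization
campaign_capital_fraction: 0.0833333333  # 1/12: one-month campaign share of annual capital
ci_confidence: 0.95
combine_ci_method: sum_bounds       # or variance_sum
tcv_code: TCV

# Allocation rules for the routine analysis (cost type -> basis).
allocation_rules:
  meetings_events: dose_proportional
  per_diem: dose_proportional
  supplies: dose_proportional
  human_resources: dose_proportional
  printing_stationery_comms: dose_proportional   # not fixed by guidance; scales with forms per child
  vehicle_rental_transport: volume_proportional
  fuel_maintenance_energy: volume_proportional
  capital_vehicles_equipment: volume_proportional

# Vaccine presentations: packed cold-chain volume per dose in cm3.
# The TCV value is a PLACEHOLDER ASSUMPTION (5-dose-vial class); no
# measured figure is published for this program. Set it explicitly for
# any real analysis.
presentations:
  - {antigen: TCV,   doses_per_vial: 5,  packed_volume_cm3_per_dose: 3.0}
  - {antigen: MRV,   doses_per_vial: 10, packed_volume_cm3_per_dose: 3.5}
  - {antigen: bOPV,  doses_per_vial: 20, packed_volume_cm3_per_dose: 1.0}
  - {antigen: PENTA, doses_per_vial: 10, packed_volume_cm3_per_dose: 2.6}
  - {antigen: PCV,   doses_per_vial: 4,  packed_volume_cm3_per_dose: 4.8}
  - {antigen: ROTA,  doses_per_vial: 1,  packed_volume_cm3_per_dose: 17.1}
  - {antigen: BCG,   doses_per_vial: 20, packed_volume_cm3_per_dose: 1.2}
  - {antigen: vitA,  doses_per_vial: 1,  packed_volume_cm3_per_dose: 0.0001}
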