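district_id: kasarani
country: Kenya
overhead_pct: 0.15
attrition_rate: 0.0
discount_rate: 0.03
useful_life_years: 10
annualize_startup: false
# GDP per capita, PPP (current international $), reference year 2012;
# run-config input with external provenance (World Bank indicator series).
gdp_per_capita: 2750.0
population:
  district: 4975
  national: 4975
printed:
  start_up_total: 988
  direct_recurrent_total: 1552
  indirect_recurrent_total: 186
  volunteer_total: 0
  overhead: 261
  total_cost: 2986
  lives_saved_total: 1.31
  per_100k_total: 26.33
  lyg_rows: {stillbirth: 11, neonatal_under_1m: 21, child_1_59m: 1, maternal: 3}
  lyg_total: 36
  incremental_cost: 2986
  icer: 82
notes:
  - >
    Lives saved are recorded at district scale as published; district and
    national populations are set equal (scale factor 1). The population
    implied by the published per-100k rates (about 4975 persons) is far
    below a plausible district population and is not reconciled by the
    source; it is recorded verbatim for per-100k consistency only.
  - >
    The published start-up subtotal (988) is 1 above the sum of its line
    items (987), a component-rounding residue transcribed as printed. The
    published grand total (2986) is consistent with the line-item sum.
  - >
    Life-table values are calibrated by inverting the published lives/LYG
    pairs through the 3% discount annuity; the small published LYG rows
    (11, 21, 1, 3) make these calibrations coarse.
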