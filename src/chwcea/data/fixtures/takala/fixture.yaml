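district_id: takala
country: Indonesia
overhead_pct: 0.15
attrition_rate: 0.0
discount_rate: 0.03
useful_life_years: 10
annualize_startup: false
# GDP per capita, PPP (current international $), reference year 2012;
# run-config input with external provenance (World Bank indicator series).
gdp_per_capita: 9426.0
population:
  district: 269596
  national: 269596
printed:
  start_up_total: 697988
  direct_recurrent_total: 3137232
  indirect_recurrent_total: 14174
  volunteer_total: 310521
  overhead: 519289
  total_cost: 4679205
  lives_saved_total: 65.35
  per_100k_total: 24.24
  lyg_rows: {stillbirth: 722, neonatal_under_1m: 1038, child_1_59m: -7, maternal: 142}
  lyg_total: 1894
  incremental_cost: 4679205
  icer: 2470
notes:
  - >
    Lives saved are recorded at district scale as published; district and
    national populations are set equal (scale factor 1), with the district
    population implied by the published per-100k rates.
  - >
    The published indirect-recurrent subtotal (14174) is 1 below the sum
    of its line items (14175); and the published per-group LYG rows sum to
    1895 while the published total is 1894. Both are component-rounding
    residues transcribed as printed.
  - >
    Life-table values are calibrated by inverting the published lives/LYG
    pairs through the 3% discount annuity.
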