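# Standard-of-care (procalcitonin) scenario: every parameter at its
# baseline value. The host-response scenario differs only in the readout
# AUROCs.
schema: triage-cim-scenario-v1
label: base_case
cohort_size: 1000
charge_test_cost: false
lr_convention: band
readouts:
  bacterial: {auroc: 0.80, n_bands: 3, lr_low: 0.1, lr_high: 10.0}
  viral: {auroc: 0.80, n_bands: 2, lr_low: 0.1, lr_high: 10.0}
  mortality: {auroc: 0.78, n_bands: 3, lr_low: 0.1, lr_high: 10.0}
epidemiology:
  p_bacterial_only: 0.25
  p_viral_only: 0.45
  p_coinfection: 0.10
  p_no_infection: 0.20
  p_mortality_risk: 0.10
clinical:
  antibiotic_days_ed: 3.18
  antibiotic_days_ward: 5.02
  antibiotic_days_icu: 6.86
  los_short_ward: 1.77
  los_icu: 4.85
  mortality_septic_icu_viral: 0.23
  mortality_reduction_timely: 0.30
  mortality_arti: 0.10
  mortality_viral: 0.067
  rehosp_icu_los: 8.30
  nonsurvivor_los: 19.90
costs:
  pcr_viral: 129.00
  blood_culture: 290.00
  oseltamivir_course: 82.00
  abx_oral_outpatient: 32.33
  abx_oral_iv_ward: 108.67
  abx_iv_icu_per_day: 277.50
  ward_day: 2285.00
  icu_day: 4300.00
  ed_visit_incl_pct: 207.00
  missed_bact_no_mort: 2869.88
  missed_bact_with_mort: 51680.76
  missed_mort_no_bact: 37730.51
  hostdx_test_cost: 0.0
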