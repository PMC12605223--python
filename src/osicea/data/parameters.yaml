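# Built-in model inputs: consolidation osimertinib vs. placebo after
# chemoradiotherapy in unresectable stage III EGFR-mutated NSCLC.
# Costs are 2024 US dollars; survival time is in months.
#
# Note on the OS rows: with S(t) = exp(-scale * t^shape) the published
# input table's two OS parameter rows are mislabelled between arms (the
# curve printed under the treated arm has the *shorter* mean survival,
# contradicting the published life-year gain of +0.45 LY = 5.4 months).
# The presets below carry the assignment that reproduces the published
# base case: osimertinib OS = (1.721e-4, 2.050), placebo OS =
# (5.603e-6, 2.931).

survival:
  osimertinib:
    os:  {scale: 0.0001721, shape: 2.050}
    pfs: {scale: 0.033281, shape: 0.849111}
  placebo:
    os:  {scale: 0.000005603, shape: 2.931}
    pfs: {scale: 0.12138, shape: 0.96416}

countries:
  usa:
    drug_cost_per_cycle: 18034.0
    ae_cost_oneoff: {osimertinib: 351.0, placebo: 0.0}
    lab_cost_per_cycle: 609.0
    radiology_cost_per_cycle: 1765.0
    bsc_cost_per_cycle: 3728.0
    palliative_cost_oneoff: 14532.0
    discount_rate_annual: 0.03
    discount_rate_costs_annual: null
    wtp_per_qaly: 150000.0
    subsequent_therapy_rate: {osimertinib: 0.294, placebo: 0.781}
    conventions:
      structure: product
      accrual: start
      time_grid: cycle_as_month
      monitoring_site: treated_pfs
      monitoring_components: lab
      pd_cost_rule: rate_weighted
      palliative: all_deaths
      cost_basis: cycle
  china:
    drug_cost_per_cycle: 685.0
    ae_cost_oneoff: {osimertinib: 48.0, placebo: 0.0}
    lab_cost_per_cycle: 609.0
    radiology_cost_per_cycle: 1765.0
    bsc_cost_per_cycle: 467.0
    palliative_cost_oneoff: 2349.0
    discount_rate_annual: 0.05
    discount_rate_costs_annual: null
    wtp_per_qaly: 39632.0
    subsequent_therapy_rate: {osimertinib: 0.294, placebo: 0.781}
    conventions:
      structure: product
      accrual: end
      time_grid: cycle_as_month
      monitoring_site: pfs
      monitoring_components: lab
      pd_cost_rule: rate_only
      palliative: all_deaths
      cost_basis: cycle

utilities:
  u_pfs: 0.791
  u_pd: 0.653
  ae_disutilities:
    - {event: diarrhea, disutility: 0.050, incidence: 0.014}
    - {event: radiation_pneumonitis, disutility: 0.090, incidence: 0.014}
    - {event: pneumonitis, disutility: 0.090, incidence: 0.014}

settings:
  cycle_length_days: 28
  horizon_years: 15
  half_cycle_correction: true
  n_cycles: 195

# One-way ranges (+/-20% unless stated) with PSA distribution families:
# costs ~ Gamma, utilities / incidences / therapy rates ~ Beta,
# discount rates ~ Uniform over their stated policy range.
ranges:
  usa.drug_cost:        {baseline: 18034.0, low: 14427.2, high: 21640.8, distribution: gamma}
  usa.ae_cost:          {baseline: 351.0,   low: 280.8,   high: 421.2,   distribution: gamma}
  usa.lab_cost:         {baseline: 609.0,   low: 487.2,   high: 730.8,   distribution: gamma}
  usa.radiology_cost:   {baseline: 1765.0,  low: 1412.0,  high: 2118.0,  distribution: gamma}
  usa.bsc_cost:         {baseline: 3728.0,  low: 2982.4,  high: 4473.6,  distribution: gamma}
  usa.palliative_cost:  {baseline: 14532.0, low: 11625.6, high: 17438.4, distribution: gamma}
  usa.discount_rate:    {baseline: 0.03,    low: 0.0,     high: 0.05,    distribution: uniform}
  china.drug_cost:       {baseline: 685.0,  low: 548.0,   high: 822.0,   distribution: gamma}
  china.ae_cost:         {baseline: 48.0,   low: 38.4,    high: 57.6,    distribution: gamma}
  china.lab_cost:        {baseline: 609.0,  low: 487.2,   high: 730.8,   distribution: gamma}
  china.radiology_cost:  {baseline: 1765.0, low: 1412.0,  high: 2118.0,  distribution: gamma}
  china.bsc_cost:        {baseline: 467.0,  low: 373.6,   high: 560.4,   distribution: gamma}
  china.palliative_cost: {baseline: 2349.0, low: 1879.2,  high: 2818.8,  distribution: gamma}
  china.discount_rate:   {baseline: 0.05,   low: 0.0,     high: 0.08,    distribution: uniform}
  utility.pfs: {baseline: 0.791, low: 0.6328, high: 0.9492, distribution: beta}
  utility.pd:  {baseline: 0.653, low: 0.5224, high: 0.7836, distribution: beta}
  disutility.diarrhea:              {baseline: 0.050, low: 0.040, high: 0.060, distribution: beta}
  disutility.radiation_pneumonitis: {baseline: 0.090, low: 0.072, high: 0.108, distribution: beta}
  disutility.pneumonitis:           {baseline: 0.090, low: 0.072, high: 0.108, distribution: beta}
  incidence.diarrhea:              {baseline: 0.014, low: 0.0112, high: 0.0168, distribution: beta}
  incidence.radiation_pneumonitis: {baseline: 0.014, low: 0.0112, high: 0.0168, distribution: beta}
  incidence.pneumonitis:           {baseline: 0.014, low: 0.0112, high: 0.0168, distribution: beta}
  rate.post_discontinuation.osimertinib: {baseline: 0.294, low: 0.235, high: 0.353, distribution: beta}
  rate.post_discontinuation.placebo:     {baseline: 0.781, low: 0.625, high: 0.937, distribution: beta}

# Trial subgroups with their PFS hazard ratios (treated vs. control);
# rows without a reported HR are carried as NA.
subgroups:
  - {label: male,                 pfs_hr: 0.26, ci_low: 0.15, ci_high: 0.46}
  - {label: female,               pfs_hr: 0.21, ci_low: 0.13, ci_high: 0.34}
  - {label: age_lt_65,            pfs_hr: 0.16, ci_low: 0.10, ci_high: 0.26}
  - {label: age_ge_65,            pfs_hr: 0.33, ci_low: 0.19, ci_high: 0.57}
  - {label: smoking_current_former, pfs_hr: 0.26, ci_low: 0.14, ci_high: 0.48}
  - {label: smoking_never,        pfs_hr: 0.22, ci_low: 0.14, ci_high: 0.34}
  - {label: stage_iiia,           pfs_hr: 0.28, ci_low: 0.15, ci_high: 0.52}
  - {label: stage_iiib_iiic,      pfs_hr: 0.21, ci_low: 0.13, ci_high: 0.33}
  - {label: egfr_exon19_deletion, pfs_hr: 0.17, ci_low: 0.10, ci_high: 0.29}
  - {label: egfr_l858r,           pfs_hr: 0.32, ci_low: 0.19, ci_high: 0.56}
  - {label: crt_concurrent,       pfs_hr: 0.25, ci_low: 0.17, ci_high: 0.36}
  - {label: crt_sequential,       pfs_hr: null}
  - {label: response_complete,    pfs_hr: null}
  - {label: response_partial,     pfs_hr: 0.20, ci_low: 0.11, ci_high: 0.34}
  - {label: response_stable,      pfs_hr: 0.18, ci_low: 0.10, ci_high: 0.30}
  - {label: response_not_evaluable, pfs_hr: null}
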