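# Default synthetic-cohort configuration.
# Anchored to the published baseline descriptives of the emulated study:
# baseline DRP total mean 2.17 (SD 1.24), course-engagement rate 0.588,
# age 63.7 (SD 7.7, floor 50), 71.6% female, annual October follow-ups
# over a rolling Oct-2019..Jun-2022 baseline window.
n_participants: 3038
seed: 0

baseline_start: "2019-10-01"
baseline_end: "2022-06-30"
followup_years: [2020, 2021, 2022]
eligibility_lead_months: 5
baseline_decay_months: 5.0
response_rates:
  2020: 0.82
  2021: 0.70
  2022: 0.985

pdmooc_rate: 0.588
pre_study_pdmooc_rate: 0.0

age_mean: 63.7
age_sd: 7.7
age_min: 50.0
age_max: 95.0
female_prop: 0.716

beta0: 2.17
beta_exposure: -0.05
beta_time: -0.10
beta_pdmooc: -0.10
beta_interaction: -0.04
sigma_u: 0.95
sigma_e: 0.70

mediation_a: 0.41
mediation_b: -0.05

generate_instruments: true
apply_missingness: true
unknown_rates:
  alcohol: 0.068
  bmi: 0.044
  hypertension: 0.005
  cholesterol: 0.006
  diabetes: 0.008
  smoking: 0.002
  cognitive_activity: 0.011
  physical_activity: 0.030
  diet: 0.005
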