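# Built-in parameter book: national scale-up of two-stage perinatal mental
# health screening plus psychosocial interventions (PSIs), Malawi, 2022-2026.
# Monetary values in Malawi Kwacha (MWK) unless the key says USD.
years: [2022, 2023, 2024, 2025, 2026]

demographic:
  population_by_year:
    2022: 20226000
    2023: 20809000
    2024: 21413000
    2025: 22036000
    2026: 22679000
  births_per_1000_2020_2025: 35.5
  births_per_1000_2025_2030: 36.0
  stillbirth_prob: 0.024
  maternal_death_prob: 0.003
  prop_period_antenatal: 0.201
  prop_period_postnatal: 0.799
  clinic_access_antenatal: 0.90
  clinic_access_postnatal: 0.72

cascade:
  screening_coverage_by_year:
    2022: 0.80
    2023: 0.85
    2024: 0.90
    2025: 0.95
    2026: 1.00
  first_stage_positive_prop: 0.24
  second_stage_positive_by_year:
    2022: 0.12
    2023: 0.14
    2024: 0.17
    2025: 0.19
    2026: 0.22
  treatment_acceptance: 0.95

service:
  first_stage_minutes: 2
  second_stage_minutes: 10
  screenings_antenatal: 4
  screenings_postnatal: 1.2
  n_sessions: 5
  individual_session_minutes: 37.5
  group_session_minutes: 75
  group_size: 6

workforce:
  direct_time_ratio_professional: 0.80
  direct_time_ratio_counsellor: 0.80
  hours_per_day_professional: 8
  hours_per_day_counsellor: 6
  days_per_year: 220
  overhead_rate: 0.15

training:
  master_classroom_hours: 40
  master_field_hours: 20
  master_supervision_training_hours: 16
  trainer_classroom_hours: 88
  trainer_field_hours: 17.5
  refresher_hours_annual: 16
  refresher_years: [2023, 2024, 2025]
  supervision_hours_per_trainee_year: 44
  participants_master_course: 12.5
  participants_trainer_course: 5
  master_fee_per_hour_mwk: 2273
  trainer_fee_per_hour_mwk: 1364
  master_monthly_salary_mwk: 400000
  trainer_monthly_salary_mwk: 240000
  fee_days_per_month: 22
  fee_hours_per_day: 8

effects:
  depression_reduction: 0.06
  extra_workdays_antenatal: 0.765
  extra_workdays_postnatal: 1.02
  diarrhoea_reduction: 0.11
  stunting_reduction: 0.05
  dw_depression: 0.40
  dw_diarrhoea: 0.19
  duration_depression_years: 0.5
  duration_diarrhoea_days: 1.44

econ:
  diarrhoea_treatment_cost_mwk: 32359
  female_daily_income_mwk: 455
  travel_cost_per_journey_mwk: 300
  gdp_per_capita_by_year:
    2022: 544
    2023: 521
    2024: 509
    2025: 505
    2026: 509
  inflation_by_year:
    2022: 0.09
    2023: 0.07
    2024: 0.06
    2025: 0.05
    2026: 0.05
  discount_rate: 0.03
  mwk_per_usd: 568.0
  usd_per_daly: 321.5
  base_year: 2022
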