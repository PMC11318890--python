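"""Parameter book: defaults, validation, serialization, fee arithmetic."""

import pydantic
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from perinatal_roi import (
    ScenarioOptions,
    hourly_fee_from_salary,
    load_parameters,
    serialize_parameters,
    validate_options,
)

# Every scalar default, addressed by dotted path (per-year series asserted
# separately below).
SCALAR_DEFAULTS = [
    ("demographic.births_per_1000_2020_2025", 35.5),
    ("demographic.births_per_1000_2025_2030", 36.0),
    ("demographic.stillbirth_prob", 0.024),
    ("demographic.maternal_death_prob", 0.003),
    ("demographic.prop_period_antenatal", 0.201),
    ("demographic.prop_period_postnatal", 0.799),
    ("demographic.clinic_access_antenatal", 0.90),
    ("demographic.clinic_access_postnatal", 0.72),
    ("cascade.first_stage_positive_prop", 0.24),
    ("cascade.treatment_acceptance", 0.95),
    ("service.first_stage_minutes", 2),
    ("service.second_stage_minutes", 10),
    ("service.screenings_antenatal", 4),
    ("service.screenings_postnatal", 1.2),
    ("service.n_sessions", 5),
    ("service.individual_session_minutes", 37.5),
    ("service.group_session_minutes", 75),
    ("service.group_size", 6),
    ("workforce.direct_time_ratio_professional", 0.80),
    ("workforce.direct_time_ratio_counsellor", 0.80),
    ("workforce.hours_per_day_professional", 8),
    ("workforce.hours_per_day_counsellor", 6),
    ("workforce.days_per_year", 220),
    ("workforce.overhead_rate", 0.15),
    ("training.master_classroom_hours", 40),
    ("training.master_field_hours", 20),
    ("training.master_supervision_training_hours", 16),
    ("training.trainer_classroom_hours", 88),
    ("training.trainer_field_hours", 17.5),
    ("training.refresher_hours_annual", 16),
    ("training.supervision_hours_per_trainee_year", 44),
    ("training.participants_master_course", 12.5),
    ("training.participants_trainer_course", 5),
    ("training.master_fee_per_hour_mwk", 2273),
    ("training.trainer_fee_per_hour_mwk", 1364),
    ("training.master_monthly_salary_mwk", 400_000),
    ("training.trainer_monthly_salary_mwk", 240_000),
    ("training.fee_days_per_month", 22),
    ("training.fee_hours_per_day", 8),
    ("effects.depression_reduction", 0.06),
    ("effects.extra_workdays_antenatal", 0.765),
    ("effects.extra_workdays_postnatal", 1.02),
    ("effects.diarrhoea_reduction", 0.11),
    ("effects.stunting_reduction", 0.05),
    ("effects.dw_depression", 0.40),
    ("effects.dw_diarrhoea", 0.19),
    ("effects.duration_depression_years", 0.5),
    ("effects.duration_diarrhoea_days", 1.44),
    ("econ.diarrhoea_treatment_cost_mwk", 32_359),
    ("econ.female_daily_income_mwk", 455),
    ("econ.travel_cost_per_journey_mwk", 300),
    ("econ.discount_rate", 0.03),
    ("econ.mwk_per_usd", 568.0),
    ("econ.usd_per_daly", 321.5),
    ("econ.base_year", 2022),
]

SERIES_DEFAULTS = [
    ("demographic.population_by_year",
     {2022: 20_226_000, 2023: 20_809_000, 2024: 21_413_000, 2025: 22_036_000, 2026: 22_679_000}),
    ("cascade.screening_coverage_by_year",
     {2022: 0.80, 2023: 0.85, 2024: 0.90, 2025: 0.95, 2026: 1.00}),
    ("cascade.second_stage_positive_by_year",
     {2022: 0.12, 2023: 0.14, 2024: 0.17, 2025: 0.19, 2026: 0.22}),
    ("econ.gdp_per_capita_by_year",
     {2022: 544, 2023: 521, 2024: 509, 2025: 505, 2026: 509}),
    ("econ.inflation_by_year",
     {2022: 0.09, 2023: 0.07, 2024: 0.06, 2025: 0.05, 2026: 0.05}),
]


def _resolve(params, path):
    node = params
    for part in path.split("."):
        node = getattr(node, part)
    return node


@pytest.mark.parametrize("path,expected", SCALAR_DEFAULTS, ids=[p for p, _ in SCALAR_DEFAULTS])
def test_default_scalar_values(defaults, path, expected):
    assert _resolve(defaults, path) == pytest.approx(expected)


@pytest.mark.parametrize("path,expected", SERIES_DEFAULTS, ids=[p for p, _ in SERIES_DEFAULTS])
def test_default_series_values(defaults, path, expected):
    assert _resolve(defaults, path) == pytest.approx(expected)


def test_default_years(defaults):
    assert defaults.years == [2022, 2023, 2024, 2025, 2026]


def test_round_trip_serialization(defaults, tmp_path):
    out = tmp_path / "params.yaml"
    serialize_parameters(defaults, out)
    assert load_parameters(out) == defaults


def test_partial_override_keeps_other_defaults(defaults, tmp_path):
    f = tmp_path / "override.yaml"
    f.write_text("econ:\n  discount_rate: 0.05\n")
    params = load_parameters(f)
    assert params.econ.discount_rate == 0.05
    reset = params.model_copy(deep=True)
    reset.econ.discount_rate = 0.03
    assert reset == defaults


def test_unknown_key_rejected(tmp_path):
    f = tmp_path / "bad.yaml"
    f.write_text("econ:\n  discont_rate: 0.05\n")
    with pytest.raises(pydantic.ValidationError, match="discont_rate"):
        load_parameters(f)


def test_bound_violation_names_field(tmp_path):
    f = tmp_path / "bad.yaml"
    f.write_text("cascade:\n  treatment_acceptance: 1.2\n")
    with pytest.raises(pydantic.ValidationError, match="treatment_acceptance"):
        load_parameters(f)


def test_malformed_yaml_reports_line(tmp_path):
    f = tmp_path / "broken.yaml"
    f.write_text("econ:\n  discount_rate: [unclosed\n")
    with pytest.raises(yaml.YAMLError):
        load_parameters(f)


def test_single_year_override_merges_into_series(defaults, tmp_path):
    """A partial per-year series overrides key-by-key, keeping the other
    years' defaults."""
    f = tmp_path / "short.yaml"
    f.write_text("demographic:\n  population_by_year: {2022: 30000000}\n")
    params = load_parameters(f)
    assert params.demographic.population_by_year[2022] == 30_000_000
    assert params.demographic.population_by_year[2023] == 20_809_000


def test_incomplete_year_series_rejected(defaults):
    data = defaults.model_dump()
    del data["demographic"]["population_by_year"][2023]
    from perinatal_roi import ParameterSet

    with pytest.raises(pydantic.ValidationError, match="population_by_year"):
        ParameterSet.model_validate(data)


@pytest.mark.parametrize(
    "salary,days,hours,expected",
    [
        (400_000, 22, 8, 2_273),
        (240_000, 22, 8, 1_364),
        (176, 22, 8, 1),
    ],
)
def test_hourly_fee_from_salary(salary, days, hours, expected):
    assert hourly_fee_from_salary(salary, days, hours) == expected


def test_hourly_fee_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        hourly_fee_from_salary(400_000, 0, 8)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    salary=st.integers(min_value=1_000, max_value=10_000_000),
    k=st.integers(min_value=1, max_value=20),
)
def test_hourly_fee_homogeneous_in_salary(salary, k):
    """Scaling the salary k-fold scales the fee k-fold, up to rounding."""
    base = hourly_fee_from_salary(salary, 22, 8)
    scaled = hourly_fee_from_salary(k * salary, 22, 8)
    assert abs(scaled - k * base) <= k  # each rounding is off by <= 1/2


@pytest.mark.parametrize("prop_group,prop_clinic", [(0.0, 1.0), (0.25, 0.75), (0.5, 0.5)])
def test_options_on_grid_accepted(prop_group, prop_clinic):
    opts = validate_options(
        {"prop_group": prop_group, "prop_clinic": prop_clinic, "salary_psi_usd_month": 40}
    )
    assert opts.prop_group == prop_group
    assert opts.salary_first_stage_usd_month == 235  # default preserved


def test_off_grid_proportion_rejected_with_allowed_levels():
    with pytest.raises(pydantic.ValidationError, match="allowed levels"):
        ScenarioOptions(prop_group=0.33)


def test_nonpositive_salary_rejected():
    with pytest.raises(pydantic.ValidationError):
        ScenarioOptions(salary_psi_usd_month=0)
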