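"""Validated parameter book and scenario options.

The model is a deterministic cost-benefit calculator: every input is a
named parameter. Parameters are grouped by domain (demography, screening
cascade, service delivery, workforce terms, training cascade, intervention
effects, economics) and ship with a complete built-in default book for the
Malawi 2022-2026 scale-up analysis. A user file overrides defaults
key-by-key; unknown keys are rejected so that a typo can never silently
fall back to a default.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._rounding import round_half_up

__all__ = [
    "DemographicParams",
    "CascadeRates",
    "ServiceParams",
    "WorkforceParams",
    "TrainingParams",
    "EffectParams",
    "EconParams",
    "ScenarioOptions",
    "ParameterSet",
    "OPTION_GRID",
    "load_parameters",
    "serialize_parameters",
    "hourly_fee_from_salary",
    "validate_options",
]

#: Allowed levels for the delivery-mix levers (format and setting).
OPTION_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DemographicParams(_StrictModel):
    """National population and perinatal demography."""

    population_by_year: dict[int, float]
    births_per_1000_2020_2025: float = Field(ge=0)
    births_per_1000_2025_2030: float = Field(ge=0)
    stillbirth_prob: float = Field(ge=0, le=1)
    maternal_death_prob: float = Field(ge=0, le=1)
    prop_period_antenatal: float = Field(ge=0, le=1)
    prop_period_postnatal: float = Field(ge=0, le=1)
    clinic_access_antenatal: float = Field(ge=0, le=1)
    clinic_access_postnatal: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "DemographicParams":
        if any(v <= 0 for v in self.population_by_year.values()):
            raise ValueError("population_by_year: populations must be strictly positive")
        if abs(self.prop_period_antenatal + self.prop_period_postnatal - 1.0) > 1e-9:
            raise ValueError(
                "prop_period_antenatal + prop_period_postnatal must equal 1"
            )
        return self


class CascadeRates(_StrictModel):
    """Screening coverage, positivity and treatment acceptance."""

    screening_coverage_by_year: dict[int, float]
    first_stage_positive_prop: float = Field(ge=0, le=1)
    second_stage_positive_by_year: dict[int, float]
    treatment_acceptance: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "CascadeRates":
        for name in ("screening_coverage_by_year", "second_stage_positive_by_year"):
            series = getattr(self, name)
            if any(not 0 <= v <= 1 for v in series.values()):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
        cov = [v for _, v in sorted(self.screening_coverage_by_year.items())]
        if any(b < a for a, b in zip(cov, cov[1:])):
            raise ValueError(
                "screening_coverage_by_year must be non-decreasing over years"
            )
        return self


class ServiceParams(_StrictModel):
    """Durations and volumes of screening contacts and PSI sessions."""

    first_stage_minutes: float = Field(gt=0)
    second_stage_minutes: float = Field(gt=0)
    screenings_antenatal: float = Field(gt=0)
    screenings_postnatal: float = Field(gt=0)
    n_sessions: float = Field(gt=0)
    individual_session_minutes: float = Field(gt=0)
    group_session_minutes: float = Field(gt=0)
    group_size: float = Field(ge=1)


class WorkforceParams(_StrictModel):
    """Statutory working terms for the two delivering cadres."""

    direct_time_ratio_professional: float = Field(gt=0, le=1)
    direct_time_ratio_counsellor: float = Field(gt=0, le=1)
    hours_per_day_professional: float = Field(gt=0, le=24)
    hours_per_day_counsellor: float = Field(gt=0, le=24)
    days_per_year: float = Field(gt=0, le=366)
    overhead_rate: float = Field(ge=0)


class TrainingParams(_StrictModel):
    """Train-the-trainer cascade: hours, class sizes, trainer fees."""

    master_classroom_hours: float = Field(ge=0)
    master_field_hours: float = Field(ge=0)
    master_supervision_training_hours: float = Field(ge=0)
    trainer_classroom_hours: float = Field(ge=0)
    trainer_field_hours: float = Field(ge=0)
    refresher_hours_annual: float = Field(ge=0)
    refresher_years: list[int]
    supervision_hours_per_trainee_year: float = Field(ge=0)
    participants_master_course: float = Field(gt=0)
    participants_trainer_course: float = Field(gt=0)
    master_fee_per_hour_mwk: float = Field(ge=0)
    trainer_fee_per_hour_mwk: float = Field(ge=0)
    master_monthly_salary_mwk: float = Field(ge=0)
    trainer_monthly_salary_mwk: float = Field(ge=0)
    fee_days_per_month: float = Field(gt=0)
    fee_hours_per_day: float = Field(gt=0)

    @property
    def master_course_hours(self) -> float:
        """Total contact hours of one master-led course (classroom + field
        + supervision training)."""
        return (
            self.master_classroom_hours
            + self.master_field_hours
            + self.master_supervision_training_hours
        )

    @property
    def trainer_course_hours(self) -> float:
        """Total contact hours of one trainer-led front-line course."""
        return self.trainer_classroom_hours + self.trainer_field_hours


class EffectParams(_StrictModel):
    """Intervention effect sizes and DALY building blocks."""

    depression_reduction: float = Field(ge=0, le=1)
    extra_workdays_antenatal: float = Field(ge=0)
    extra_workdays_postnatal: float = Field(ge=0)
    diarrhoea_reduction: float = Field(ge=0, le=1)
    stunting_reduction: float = Field(ge=0, le=1)
    dw_depression: float = Field(ge=0, le=1)
    dw_diarrhoea: float = Field(ge=0, le=1)
    duration_depression_years: float = Field(gt=0)
    duration_diarrhoea_days: float = Field(gt=0)


class EconParams(_StrictModel):
    """Unit costs, valuation rates, exchange rate, inflation and discounting."""

    diarrhoea_treatment_cost_mwk: float = Field(ge=0)
    female_daily_income_mwk: float = Field(ge=0)
    travel_cost_per_journey_mwk: float = Field(ge=0)
    gdp_per_capita_by_year: dict[int, float]
    inflation_by_year: dict[int, float]
    discount_rate: float = Field(ge=0)
    mwk_per_usd: float = Field(gt=0)
    usd_per_daly: float = Field(ge=0)
    base_year: int


class ScenarioOptions(_StrictModel):
    """The four user-selectable levers of the calculator.

    Salaries are monthly USD amounts; the delivery-mix levers are
    proportions restricted to the five-level grid 0/25/50/75/100%.
    ``prop_group`` is the share of women treated in group sessions,
    ``prop_clinic`` the share treated at the clinic (the rest in the
    community).
    """

    salary_first_stage_usd_month: float = Field(default=235, gt=0)
    salary_psi_usd_month: float = Field(default=40, gt=0)
    prop_group: float = 0.5
    prop_clinic: float = 0.5

    @model_validator(mode="after")
    def _on_grid(self) -> "ScenarioOptions":
        for name in ("prop_group", "prop_clinic"):
            v = getattr(self, name)
            if not any(abs(v - g) <= 1e-12 for g in OPTION_GRID):
                allowed = ", ".join(f"{g:.2f}" for g in OPTION_GRID)
                raise ValueError(f"{name}={v!r} is off-grid; allowed levels: {allowed}")
        return self


class ParameterSet(_StrictModel):
    """The complete parameter book for one model run."""

    years: list[int]
    demographic: DemographicParams
    cascade: CascadeRates
    service: ServiceParams
    workforce: WorkforceParams
    training: TrainingParams
    effects: EffectParams
    econ: EconParams

    @model_validator(mode="after")
    def _series_cover_years(self) -> "ParameterSet":
        if not self.years or self.years != sorted(self.years):
            raise ValueError("years must be a non-empty, increasing list")
        expected = set(self.years)
        series = {
            "demographic.population_by_year": self.demographic.population_by_year,
            "cascade.screening_coverage_by_year": self.cascade.screening_coverage_by_year,
            "cascade.second_stage_positive_by_year": self.cascade.second_stage_positive_by_year,
            "econ.gdp_per_capita_by_year": self.econ.gdp_per_capita_by_year,
            "econ.inflation_by_year": self.econ.inflation_by_year,
        }
        for name, s in series.items():
            if set(s) != expected:
                raise ValueError(f"{name} must cover exactly the modelled years {self.years}")
        if self.econ.base_year != self.years[0]:
            raise ValueError("econ.base_year must be the first modelled year")
        return self


def _default_mapping() -> dict[str, Any]:
    source = importlib.resources.files("perinatal_roi").joinpath("data/defaults.yaml")
    return yaml.safe_load(source.read_text(encoding="utf-8"))


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(base)
    for key, value in override.items():
        if key in merged and isinstance(merged[key], dict) and isinstance(value, Mapping):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet`, optionally overriding the defaults.

    Parameters
    ----------
    path
        YAML file with any subset of the parameter book, nested by section.
        Absent keys keep their built-in default; keys unknown to the schema
        raise a validation error.

    Raises
    ------
    yaml.YAMLError
        If the file is not valid YAML (the message names the offending line).
    pydantic.ValidationError
        If a value violates its bound or a key is unknown.
    """
    data = _default_mapping()
    if path is not None:
        override = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if override is None:
            override = {}
        if not isinstance(override, Mapping):
            raise TypeError(f"{path}: top level must be a mapping of sections")
        data = _deep_merge(data, override)
    return ParameterSet.model_validate(data)


def serialize_parameters(params: ParameterSet, path: str | Path | None = None) -> str:
    """Serialize a parameter set to YAML; round-trips through
    :func:`load_parameters` to an identical set."""
    text = yaml.safe_dump(params.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def hourly_fee_from_salary(
    monthly_salary: float, days_per_month: float, hours_per_day: float
) -> int:
    """Convert a monthly salary to an hourly fee in whole MWK.

    The convention used throughout the costing: a month has
    ``days_per_month`` paid days of ``hours_per_day`` hours, and the fee is
    rounded to the nearest whole kwacha (half away from zero).
    """
    if monthly_salary <= 0 or days_per_month <= 0 or hours_per_day <= 0:
        raise ValueError("salary, days and hours must all be positive")
    return round_half_up(monthly_salary / (days_per_month * hours_per_day))


def validate_options(options: ScenarioOptions | Mapping[str, Any]) -> ScenarioOptions:
    """Validate scenario options, coercing a plain mapping if given."""
    if isinstance(options, ScenarioOptions):
        return ScenarioOptions.model_validate(options.model_dump())
    return ScenarioOptions.model_validate(dict(options))
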