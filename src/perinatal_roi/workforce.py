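"""Workforce time and staffing costs.

Service volumes are converted into practitioner workdays, workdays into
whole full-time equivalents (FTEs), and FTEs into annual salary costs.
Two cadres are modelled: health professionals (e.g. midwives) who deliver
the brief first-stage screen during routine visits at 8 scheduled hours a
day, and trained volunteers/counsellors who deliver the second-stage
screen and the psychosocial intervention at 6 scheduled hours a day.

Workday conversion divides demanded minutes by scheduled daily hours; the
direct-time ratio (share of paid time available for client-facing work)
enters only when converting workdays into FTEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._rounding import round_half_up
from .cascade import CascadeYear
from .parameters import ParameterSet, ScenarioOptions, ServiceParams

__all__ = [
    "WorkloadYear",
    "screening_workdays",
    "minutes_to_workdays",
    "treatment_minutes_per_woman",
    "fte_required",
    "annual_staff_cost",
    "project_workload",
]


@dataclass(frozen=True)
class WorkloadYear:
    """Workforce demand and staffing cost for one calendar year."""

    year: int
    first_stage_days: int
    second_stage_and_treatment_days: int
    professionals_fte: int
    volunteers_fte: int
    staff_cost_mwk: float

    def __post_init__(self) -> None:
        if self.first_stage_days < 0 or self.second_stage_and_treatment_days < 0:
            raise ValueError(f"{self.year}: workdays must be non-negative")
        if self.professionals_fte < 0 or self.volunteers_fte < 0:
            raise ValueError(f"{self.year}: FTE counts must be non-negative")


def minutes_to_workdays(total_minutes: float, hours_per_day: float) -> int:
    """Convert demanded minutes into whole workdays at the cadre's
    scheduled daily hours."""
    if hours_per_day <= 0:
        raise ValueError("hours_per_day must be positive")
    if total_minutes < 0:
        raise ValueError("total_minutes must be non-negative")
    return round_half_up(total_minutes / (hours_per_day * 60.0))


def screening_workdays(
    n_screenings: float, minutes_each: float, hours_per_day: float
) -> int:
    """Workdays needed to deliver ``n_screenings`` of ``minutes_each``."""
    if n_screenings < 0 or minutes_each < 0:
        raise ValueError("inputs must be non-negative")
    return minutes_to_workdays(n_screenings * minutes_each, hours_per_day)


def treatment_minutes_per_woman(prop_group: float, service: ServiceParams) -> float:
    """Provider minutes per treated woman under the group/individual mix.

    A course is ``n_sessions`` sessions. Group sessions pool ``group_size``
    women per provider session, so per-woman provider time is the session
    length divided by the group size.
    """
    if service.group_size <= 0:
        raise ValueError("group_size must be positive")
    group = service.n_sessions * service.group_session_minutes / service.group_size
    individual = service.n_sessions * service.individual_session_minutes
    return prop_group * group + (1.0 - prop_group) * individual


def fte_required(workdays: float, days_per_year: float, direct_time_ratio: float) -> int:
    """Whole persons needed to supply ``workdays`` of direct time.

    Only ``direct_time_ratio`` of an employee's ``days_per_year`` is
    client-facing; people are indivisible, so the quotient is rounded up.
    """
    if days_per_year <= 0 or direct_time_ratio <= 0:
        raise ValueError("days_per_year and direct_time_ratio must be positive")
    if workdays < 0:
        raise ValueError("workdays must be non-negative")
    return math.ceil(workdays / (days_per_year * direct_time_ratio))


def annual_staff_cost(
    fte: float, monthly_salary_usd: float, overhead_rate: float, mwk_per_usd: float
) -> float:
    """Annual employment cost in MWK: salary x 12 months x (1 + overhead),
    converted at the model exchange rate."""
    if fte < 0 or monthly_salary_usd < 0 or overhead_rate < 0 or mwk_per_usd < 0:
        raise ValueError("inputs must be non-negative")
    return fte * monthly_salary_usd * 12.0 * (1.0 + overhead_rate) * mwk_per_usd


def project_workload(
    cascade: list[CascadeYear], params: ParameterSet, options: ScenarioOptions
) -> list[WorkloadYear]:
    """Workforce demand and cost for every modelled year.

    Second-stage screening and treatment minutes are pooled into one
    volunteer/counsellor workload, mirroring how the cadre is deployed.
    """
    wf, service = params.workforce, params.service
    per_woman = treatment_minutes_per_woman(options.prop_group, service)
    out: list[WorkloadYear] = []
    for cy in cascade:
        first_days = screening_workdays(
            cy.first_stage_screenings,
            service.first_stage_minutes,
            wf.hours_per_day_professional,
        )
        volunteer_minutes = (
            cy.second_stage_screenings * service.second_stage_minutes
            + cy.women_treated * per_woman
        )
        volunteer_days = minutes_to_workdays(volunteer_minutes, wf.hours_per_day_counsellor)
        prof_fte = fte_required(first_days, wf.days_per_year, wf.direct_time_ratio_professional)
        vol_fte = fte_required(volunteer_days, wf.days_per_year, wf.direct_time_ratio_counsellor)
        cost = annual_staff_cost(
            prof_fte,
            options.salary_first_stage_usd_month,
            wf.overhead_rate,
            params.econ.mwk_per_usd,
        ) + annual_staff_cost(
            vol_fte,
            options.salary_psi_usd_month,
            wf.overhead_rate,
            params.econ.mwk_per_usd,
        )
        out.append(
            WorkloadYear(
                year=cy.year,
                first_stage_days=first_days,
                second_stage_and_treatment_days=volunteer_days,
                professionals_fte=prof_fte,
                volunteers_fte=vol_fte,
                staff_cost_mwk=cost,
            )
        )
    return out
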