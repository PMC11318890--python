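"""Train-the-trainer cascade and supervision costing.

One master trainer (a clinical psychologist, paid an hourly fee) trains
trainers (professional assistant counsellors); trainers train and then
continuously supervise the front-line deliverers. Course costs comprise
the deliverer's fee for the course hours plus the trainees' time valued
at their own hourly wage. The first modelled year trains the whole
initial workforce; later years train only the workforce increment, plus
annual refresher courses during the configured refresher window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .parameters import TrainingParams, hourly_fee_from_salary

__all__ = [
    "TrainingCostYear",
    "new_trainees",
    "course_cost",
    "supervision_cost",
    "annual_training_cost",
    "project_training",
]


@dataclass(frozen=True)
class TrainingCostYear:
    """Training and supervision costs for one calendar year."""

    year: int
    new_trainees: int
    master_courses: int
    trainer_courses: int
    training_cost_mwk: float
    supervision_cost_mwk: float

    def __post_init__(self) -> None:
        if self.training_cost_mwk < 0 or self.supervision_cost_mwk < 0:
            raise ValueError(f"{self.year}: costs must be non-negative")


def new_trainees(fte_series: Sequence[int]) -> list[int]:
    """Persons to train each year: the full workforce in year one, then
    only the year-on-year increment (never negative)."""
    if any(f < 0 for f in fte_series):
        raise ValueError("FTE series must be non-negative")
    out: list[int] = []
    for i, fte in enumerate(fte_series):
        out.append(fte if i == 0 else max(0, fte - fte_series[i - 1]))
    return out


def course_cost(
    trainer_fee: float,
    trainer_hours: float,
    trainee_hourly_cost: float,
    trainee_hours: float,
    n_trainees: float,
) -> float:
    """Cost of one training course: deliverer fee for the course hours plus
    all trainees' attendance time at their hourly cost."""
    if min(trainer_fee, trainer_hours, trainee_hourly_cost, trainee_hours, n_trainees) < 0:
        raise ValueError("inputs must be non-negative")
    return trainer_fee * trainer_hours + n_trainees * trainee_hourly_cost * trainee_hours


def supervision_cost(
    n_staff: float, hours_per_year: float, trainer_fee: float, trainee_hourly_cost: float
) -> float:
    """Annual one-to-one supervision cost: for each supervised staff member,
    the supervising trainer's fee and the supervisee's time over the
    annual supervision hours."""
    if min(n_staff, hours_per_year, trainer_fee, trainee_hourly_cost) < 0:
        raise ValueError("inputs must be non-negative")
    return n_staff * hours_per_year * (trainer_fee + trainee_hourly_cost)


def annual_training_cost(
    year: int,
    new_frontline: int,
    new_trainers: int,
    existing_staff: int,
    trainee_hourly_cost: float,
    params: TrainingParams,
) -> float:
    """Total training cost for one year.

    Sums master-led courses for new trainers (trainer trainees costed at
    the trainer hourly fee), trainer-led courses for new front-line
    deliverers (costed at ``trainee_hourly_cost``), and — in refresher
    years — refresher courses for the existing front-line workforce.
    """
    cost = 0.0
    if new_trainers > 0:
        n_master = math.ceil(new_trainers / params.participants_master_course)
        cost += n_master * params.master_fee_per_hour_mwk * params.master_course_hours
        cost += (
            new_trainers * params.trainer_fee_per_hour_mwk * params.master_course_hours
        )
    if new_frontline > 0:
        n_courses = math.ceil(new_frontline / params.participants_trainer_course)
        cost += n_courses * params.trainer_fee_per_hour_mwk * params.trainer_course_hours
        cost += new_frontline * trainee_hourly_cost * params.trainer_course_hours
    if year in params.refresher_years and existing_staff > 0:
        n_refresher = math.ceil(existing_staff / params.participants_trainer_course)
        cost += params.refresher_hours_annual * (
            n_refresher * params.trainer_fee_per_hour_mwk
            + existing_staff * trainee_hourly_cost
        )
    return cost


def project_training(
    years: Sequence[int],
    frontline_fte: Sequence[int],
    params: TrainingParams,
    frontline_salary_usd_month: float,
    mwk_per_usd: float,
) -> list[TrainingCostYear]:
    """Training and supervision costs for every modelled year.

    The trainer pool is sized to the front-line workforce (one trainer per
    trainer-course class of deliverers); trainers provide both training
    and all ongoing supervision.
    """
    if len(years) != len(frontline_fte):
        raise ValueError("years and FTE series must have equal length")
    trainee_hourly = hourly_fee_from_salary(
        frontline_salary_usd_month * mwk_per_usd,
        params.fee_days_per_month,
        params.fee_hours_per_day,
    )
    trainers = [
        math.ceil(f / params.participants_trainer_course) for f in frontline_fte
    ]
    frontline_new = new_trainees(frontline_fte)
    trainers_new = new_trainees(trainers)
    out: list[TrainingCostYear] = []
    for i, year in enumerate(years):
        master_courses = (
            math.ceil(trainers_new[i] / params.participants_master_course)
            if trainers_new[i]
            else 0
        )
        trainer_courses = (
            math.ceil(frontline_new[i] / params.participants_trainer_course)
            if frontline_new[i]
            else 0
        )
        training = annual_training_cost(
            year, frontline_new[i], trainers_new[i], frontline_fte[i], trainee_hourly, params
        )
        supervision = supervision_cost(
            frontline_fte[i],
            params.supervision_hours_per_trainee_year,
            params.trainer_fee_per_hour_mwk,
            trainee_hourly,
        )
        out.append(
            TrainingCostYear(
                year=year,
                new_trainees=frontline_new[i],
                master_courses=master_courses,
                trainer_courses=trainer_courses,
                training_cost_mwk=training,
                supervision_cost_mwk=supervision,
            )
        )
    return out
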