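"""Health and economic consequences of treating women with PSIs.

All consequences accrue in the year the intervention is delivered
(a deliberately conservative one-year horizon): maternal depression
episodes averted and the DALYs they carry; infant diarrhoea episodes
averted, their DALYs and the healthcare expenditure saved; mothers'
productivity regained; and stunting cases averted, which are reported as
a count but never monetized. Reductions in excess maternal mortality are
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rounding import round_half_up
from .cascade import CascadeYear
from .parameters import ParameterSet

__all__ = [
    "BenefitYear",
    "depression_episodes_averted",
    "dalys_averted",
    "total_dalys",
    "healthcare_savings",
    "productivity_gain",
    "stunting_averted",
    "monetize_dalys",
    "project_benefits",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class BenefitYear:
    """Health and economic benefits for one calendar year."""

    year: int
    depression_episodes_averted: int
    mother_dalys: float
    diarrhoea_episodes_averted: int
    child_dalys: float
    total_dalys: int
    health_benefit_usd: float
    healthcare_savings_mwk: float
    extra_workdays: int
    productivity_gain_mwk: float
    stunting_averted: int


def depression_episodes_averted(women_treated: float, reduction: float) -> int:
    """Maternal depression episodes averted: the absolute remission
    difference applied to every treated woman."""
    if not 0 <= reduction <= 1:
        raise ValueError("reduction must lie in [0, 1]")
    return round_half_up(women_treated * reduction)


def dalys_averted(episodes: float, disability_weight: float, duration_years: float) -> float:
    """DALYs averted = episodes x disability weight x duration in years."""
    if not 0 <= disability_weight <= 1:
        raise ValueError("disability weight must lie in [0, 1]")
    if duration_years < 0:
        raise ValueError("duration must be non-negative")
    return episodes * disability_weight * duration_years


def total_dalys(mother: float, child: float) -> int:
    """Total DALYs averted across mothers and infants, rounded."""
    return round_half_up(mother + child)


def healthcare_savings(diarrhoea_episodes_averted: float, unit_cost: float) -> float:
    """Hospital expenditure saved on averted infant diarrhoea episodes."""
    if diarrhoea_episodes_averted < 0 or unit_cost < 0:
        raise ValueError("inputs must be non-negative")
    return diarrhoea_episodes_averted * unit_cost


def productivity_gain(
    women_treated: float,
    extra_days_ante: float,
    extra_days_post: float,
    daily_income: float,
) -> tuple[int, float]:
    """(extra workdays, MWK value) from reduced maternal work absence."""
    if min(women_treated, extra_days_ante, extra_days_post, daily_income) < 0:
        raise ValueError("inputs must be non-negative")
    days = round_half_up(women_treated * (extra_days_ante + extra_days_post))
    return days, days * daily_income


def stunting_averted(women_treated: float, reduction: float) -> int:
    """Child stunting cases averted; reported but never monetized."""
    if not 0 <= reduction <= 1:
        raise ValueError("reduction must lie in [0, 1]")
    return round_half_up(women_treated * reduction)


def monetize_dalys(dalys: float, usd_per_daly: float) -> float:
    """Monetary value (USD) of averted DALYs."""
    if dalys < 0 or usd_per_daly < 0:
        raise ValueError("inputs must be non-negative")
    return dalys * usd_per_daly


def project_benefits(cascade: list[CascadeYear], params: ParameterSet) -> list[BenefitYear]:
    """Health and economic benefits for every modelled year."""
    eff, econ = params.effects, params.econ
    out: list[BenefitYear] = []
    for cy in cascade:
        depression = depression_episodes_averted(cy.women_treated, eff.depression_reduction)
        mother = dalys_averted(depression, eff.dw_depression, eff.duration_depression_years)
        diarrhoea = round_half_up(cy.women_treated * eff.diarrhoea_reduction)
        child = dalys_averted(
            diarrhoea, eff.dw_diarrhoea, eff.duration_diarrhoea_days / DAYS_PER_YEAR
        )
        dalys = total_dalys(mother, child)
        days, gain = productivity_gain(
            cy.women_treated,
            eff.extra_workdays_antenatal,
            eff.extra_workdays_postnatal,
            econ.female_daily_income_mwk,
        )
        out.append(
            BenefitYear(
                year=cy.year,
                depression_episodes_averted=depression,
                mother_dalys=mother,
                diarrhoea_episodes_averted=diarrhoea,
                child_dalys=child,
                total_dalys=dalys,
                health_benefit_usd=monetize_dalys(dalys, econ.usd_per_daly),
                healthcare_savings_mwk=healthcare_savings(
                    diarrhoea, econ.diarrhoea_treatment_cost_mwk
                ),
                extra_workdays=days,
                productivity_gain_mwk=gain,
                stunting_averted=stunting_averted(cy.women_treated, eff.stunting_reduction),
            )
        )
    return out
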