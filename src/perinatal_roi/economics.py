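"""Currency conversion, discounting and the headline aggregates.

Costs are accumulated in MWK and converted to USD at the model exchange
rate. Benefits (DALY value, healthcare savings, productivity) are summed
in USD. Net benefit is benefits minus costs, undiscounted; the net
present value deflates the net benefit to base-year prices using the
cumulative consumer-price-index factor and then discounts it to the base
year. The return-on-investment ratio is benefits divided by costs, so
ROI >= 1 exactly when the net benefit is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._rounding import round_half_up
from .benefits import BenefitYear
from .parameters import EconParams
from .training import TrainingCostYear
from .travel import TravelCostYear
from .workforce import WorkloadYear

__all__ = [
    "EconomicSummary",
    "to_usd",
    "sum_costs",
    "net_benefit",
    "discount_factor",
    "inflation_factor",
    "present_value",
    "roi",
    "project_economics",
]


@dataclass(frozen=True)
class EconomicSummary:
    """Headline economics for one calendar year. ``roi`` is ``None`` when
    total costs are zero (the ratio is undefined)."""

    year: int
    total_costs_mwk: float
    total_costs_usd: int
    total_benefits_usd: int
    net_benefit_usd: int
    npv_usd: int
    roi: Optional[float]


def to_usd(amount_mwk: float, mwk_per_usd: float) -> float:
    """Convert MWK to USD at the model exchange rate."""
    if mwk_per_usd <= 0:
        raise ValueError("mwk_per_usd must be positive")
    return amount_mwk / mwk_per_usd


def sum_costs(staff: float, training: float, supervision: float, travel: float) -> float:
    """Aggregate the four cost categories (MWK)."""
    if min(staff, training, supervision, travel) < 0:
        raise ValueError("cost components must be non-negative")
    return staff + training + supervision + travel


def net_benefit(total_benefits_usd: float, total_costs_usd: float) -> float:
    """Undiscounted net benefit: benefits minus costs."""
    return total_benefits_usd - total_costs_usd


def discount_factor(year: int, base_year: int, rate: float) -> float:
    """Discount factor to the base year at the annual ``rate``."""
    if year < base_year:
        raise ValueError("year must not precede the base year")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return 1.0 / (1.0 + rate) ** (year - base_year)


def inflation_factor(year: int, econ: EconParams) -> float:
    """Cumulative CPI factor from the base year to ``year``: the product
    of (1 + inflation) over the years after the base year up to ``year``.
    The base year itself is 1."""
    factor = 1.0
    for y in sorted(econ.inflation_by_year):
        if econ.base_year < y <= year:
            factor *= 1.0 + econ.inflation_by_year[y]
    return factor


def present_value(nominal_usd: float, year: int, econ: EconParams) -> float:
    """Express a nominal USD amount in discounted base-year prices:
    deflate by cumulative inflation, then discount."""
    return (
        nominal_usd
        / inflation_factor(year, econ)
        * discount_factor(year, econ.base_year, econ.discount_rate)
    )


def roi(total_benefits_usd: float, total_costs_usd: float) -> Optional[float]:
    """Return-on-investment ratio (benefits / costs); ``None`` when costs
    are zero."""
    if total_costs_usd == 0:
        return None
    return total_benefits_usd / total_costs_usd


def project_economics(
    workload: list[WorkloadYear],
    training: list[TrainingCostYear],
    travel: list[TravelCostYear],
    benefits: list[BenefitYear],
    econ: EconParams,
) -> list[EconomicSummary]:
    """Headline aggregates for every modelled year.

    USD totals are reported in whole dollars (rounded half away from
    zero); the ROI ratio keeps full precision.
    """
    out: list[EconomicSummary] = []
    for wl, tr, tv, bn in zip(workload, training, travel, benefits):
        costs_mwk = sum_costs(
            wl.staff_cost_mwk, tr.training_cost_mwk, tr.supervision_cost_mwk, tv.travel_cost_mwk
        )
        costs_usd = round_half_up(to_usd(costs_mwk, econ.mwk_per_usd))
        benefits_usd = round_half_up(
            bn.health_benefit_usd
            + to_usd(bn.healthcare_savings_mwk, econ.mwk_per_usd)
            + to_usd(bn.productivity_gain_mwk, econ.mwk_per_usd)
        )
        nb = round_half_up(net_benefit(benefits_usd, costs_usd))
        out.append(
            EconomicSummary(
                year=wl.year,
                total_costs_mwk=costs_mwk,
                total_costs_usd=costs_usd,
                total_benefits_usd=benefits_usd,
                net_benefit_usd=nb,
                npv_usd=round_half_up(present_value(nb, wl.year, econ)),
                roi=roi(benefits_usd, costs_usd),
            )
        )
    return out
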