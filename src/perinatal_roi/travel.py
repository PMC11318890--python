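"""Travel costs of delivering psychosocial interventions.

Clinic-delivered sessions make the woman travel (an out-of-pocket,
societal cost); community-delivered sessions make the provider travel.
Community group sessions pool one provider journey per group session.
Screening visits incur no travel cost: they happen at visits women make
anyway as part of routine maternal care.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rounding import round_half_up
from .cascade import CascadeYear
from .parameters import ParameterSet, ScenarioOptions, ServiceParams

__all__ = ["TravelCostYear", "travel_cost", "travel_journeys", "project_travel"]


@dataclass(frozen=True)
class TravelCostYear:
    """Journeys and travel cost for one calendar year.

    Journey counts may be fractional: community group delivery averages
    one provider journey over ``group_size`` women.
    """

    year: int
    journeys_women: float
    journeys_providers: float
    travel_cost_mwk: float

    def __post_init__(self) -> None:
        if min(self.journeys_women, self.journeys_providers, self.travel_cost_mwk) < 0:
            raise ValueError(f"{self.year}: travel quantities must be non-negative")


def travel_journeys(
    women_treated: float,
    prop_clinic: float,
    prop_group: float,
    service: ServiceParams,
) -> tuple[float, float]:
    """(women's journeys, providers' journeys) for one year.

    Women travel once per session for the clinic share, regardless of
    format (each group member attends in person). Providers travel once
    per woman-session for community individual delivery and once per group
    session (1/group_size per woman-session) for community group delivery.
    Group sessions at clinics need no provider journey: the provider is
    on-site.
    """
    if service.group_size <= 0:
        raise ValueError("group_size must be positive")
    sessions = service.n_sessions
    women_j = women_treated * prop_clinic * sessions
    provider_j = women_treated * (1.0 - prop_clinic) * (
        (1.0 - prop_group) * sessions + prop_group * sessions / service.group_size
    )
    return women_j, provider_j


def travel_cost(
    women_treated: float,
    prop_clinic: float,
    prop_group: float,
    service: ServiceParams,
    cost_per_journey: float,
) -> int:
    """Total travel cost in MWK: one single trip per journey."""
    if women_treated < 0 or cost_per_journey < 0:
        raise ValueError("inputs must be non-negative")
    women_j, provider_j = travel_journeys(women_treated, prop_clinic, prop_group, service)
    return round_half_up((women_j + provider_j) * cost_per_journey)


def project_travel(
    cascade: list[CascadeYear], params: ParameterSet, options: ScenarioOptions
) -> list[TravelCostYear]:
    """Travel journeys and cost for every modelled year."""
    out: list[TravelCostYear] = []
    for cy in cascade:
        women_j, provider_j = travel_journeys(
            cy.women_treated, options.prop_clinic, options.prop_group, params.service
        )
        out.append(
            TravelCostYear(
                year=cy.year,
                journeys_women=women_j,
                journeys_providers=provider_j,
                travel_cost_mwk=round_half_up(
                    (women_j + provider_j) * params.econ.travel_cost_per_journey_mwk
                ),
            )
        )
    return out
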