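"""Population and screening-cascade projection.

Per modelled year the module derives: live births from UN population
projections and crude birth rates; women in the antenatal and postnatal
periods (adjusting for stillbirth and maternal mortality); the number of
first-stage screenings delivered at routine antenatal/postnatal clinic
visits; second-stage confirmatory screenings; and the number of women who
screen positive and accept a psychosocial intervention.

Counts are rounded half away from zero at each reported quantity; products
within a quantity keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rounding import round_half_up
from .parameters import ParameterSet

__all__ = [
    "CascadeYear",
    "live_births",
    "birth_rate_for_year",
    "perinatal_women",
    "coverage_at",
    "first_stage_screenings",
    "second_stage_screenings",
    "women_treated",
    "project_cascade",
]

# Crude birth rate regimes: the 2020-2025 rate applies through 2025, the
# 2025-2030 rate from 2026 onwards (reproduces the published live-birth
# series for both regime endpoints).
_BIRTH_RATE_SWITCH_YEAR = 2026


@dataclass(frozen=True)
class CascadeYear:
    """Screening-cascade volumes for one calendar year."""

    year: int
    live_births: int
    antenatal_women: int
    postnatal_women: int
    first_stage_screenings: int
    second_stage_screenings: int
    second_stage_positives: int
    women_treated: int

    def __post_init__(self) -> None:
        counts = (
            self.live_births,
            self.antenatal_women,
            self.postnatal_women,
            self.first_stage_screenings,
            self.second_stage_screenings,
            self.second_stage_positives,
            self.women_treated,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.year}: cascade counts must be non-negative")
        if self.second_stage_screenings > self.first_stage_screenings:
            raise ValueError(f"{self.year}: second-stage screenings exceed first-stage")
        if self.women_treated > self.second_stage_positives:
            raise ValueError(f"{self.year}: women treated exceed second-stage positives")


def birth_rate_for_year(year: int, params: ParameterSet) -> float:
    """Crude birth rate (per 1,000 population) applicable in ``year``."""
    demo = params.demographic
    if year < _BIRTH_RATE_SWITCH_YEAR:
        return demo.births_per_1000_2020_2025
    return demo.births_per_1000_2025_2030


def live_births(population: float, births_per_1000: float) -> int:
    """Live births = population / 1,000 x crude birth rate, rounded."""
    if population < 0 or births_per_1000 < 0:
        raise ValueError("population and birth rate must be non-negative")
    return round_half_up(population / 1000.0 * births_per_1000)


def perinatal_women(
    n_live_births: float, stillbirth_prob: float, maternal_death_prob: float
) -> tuple[int, int]:
    """Women in the antenatal and postnatal periods in a year.

    Antenatal women are all pregnancies, including those that end in
    stillbirth, so live births are inflated by ``1/(1 - stillbirth_prob)``.
    Postnatal women are mothers of live births who survive the perinatal
    period, so live births are deflated by ``1 - maternal_death_prob``.
    """
    if not 0 <= stillbirth_prob < 1:
        raise ValueError("stillbirth_prob must lie in [0, 1)")
    if not 0 <= maternal_death_prob <= 1:
        raise ValueError("maternal_death_prob must lie in [0, 1]")
    antenatal = round_half_up(n_live_births / (1.0 - stillbirth_prob))
    postnatal = round_half_up(n_live_births * (1.0 - maternal_death_prob))
    return antenatal, postnatal


def coverage_at(year: int, series: dict[int, float]) -> float:
    """Value of a per-year probability series at ``year``.

    Tabulated years return the tabulated value; a year strictly between two
    tabulated years is linearly interpolated. Years outside the tabulated
    range are a domain error.
    """
    if not series:
        raise ValueError("empty series")
    if year in series:
        return series[year]
    years = sorted(series)
    if year < years[0] or year > years[-1]:
        raise ValueError(f"year {year} outside tabulated range {years[0]}-{years[-1]}")
    lo = max(y for y in years if y < year)
    hi = min(y for y in years if y > year)
    frac = (year - lo) / (hi - lo)
    return series[lo] + frac * (series[hi] - series[lo])


def first_stage_screenings(
    antenatal_women: float,
    postnatal_women: float,
    params: ParameterSet,
    coverage: float,
    calibration_factor: float = 1.0,
) -> int:
    """First-stage (2-minute) screenings delivered in a year.

    Every clinic visit during the perinatal period carries one brief
    screen, so the count is the number of antenatal plus postnatal visits
    among women who access clinics, scaled by the screening coverage for
    the year. ``calibration_factor`` (default 1) is a hook for users who
    wish to rescale the volume towards external workbook figures; it is
    never applied by default.
    """
    demo, service = params.demographic, params.service
    visits = (
        antenatal_women * demo.clinic_access_antenatal * service.screenings_antenatal
        + postnatal_women * demo.clinic_access_postnatal * service.screenings_postnatal
    )
    return round_half_up(visits * coverage * calibration_factor)


def second_stage_screenings(first_stage: float, first_stage_positive_prop: float) -> int:
    """Second-stage (10-minute) confirmatory screenings: the proportion of
    first-stage screens that are positive."""
    if first_stage < 0 or not 0 <= first_stage_positive_prop <= 1:
        raise ValueError("invalid first-stage count or positivity proportion")
    return round_half_up(first_stage * first_stage_positive_prop)


def women_treated(
    second_stage: float, second_stage_positive_prop: float, acceptance: float
) -> int:
    """Women entering the intervention: second-stage positives times the
    treatment-acceptance probability."""
    if not 0 <= second_stage_positive_prop <= 1 or not 0 <= acceptance <= 1:
        raise ValueError("proportions must lie in [0, 1]")
    return round_half_up(second_stage * second_stage_positive_prop * acceptance)


def project_cascade(
    params: ParameterSet, calibration_factor: float = 1.0
) -> list[CascadeYear]:
    """Project the full screening cascade for every modelled year."""
    out: list[CascadeYear] = []
    for year in params.years:
        births = live_births(
            params.demographic.population_by_year[year],
            birth_rate_for_year(year, params),
        )
        ante, post = perinatal_women(
            births,
            params.demographic.stillbirth_prob,
            params.demographic.maternal_death_prob,
        )
        cov = coverage_at(year, params.cascade.screening_coverage_by_year)
        first = first_stage_screenings(ante, post, params, cov, calibration_factor)
        second = second_stage_screenings(first, params.cascade.first_stage_positive_prop)
        positives = round_half_up(
            second * coverage_at(year, params.cascade.second_stage_positive_by_year)
        )
        treated = women_treated(
            second,
            coverage_at(year, params.cascade.second_stage_positive_by_year),
            params.cascade.treatment_acceptance,
        )
        out.append(
            CascadeYear(
                year=year,
                live_births=births,
                antenatal_women=ante,
                postnatal_women=post,
                first_stage_screenings=first,
                second_stage_screenings=second,
                second_stage_positives=positives,
                women_treated=treated,
            )
        )
    return out
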