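"""Screening-cascade arithmetic and projection invariants."""

from decimal import ROUND_HALF_UP, Decimal

import pytest

from perinatal_roi import load_parameters, project_cascade
from perinatal_roi.cascade import (
    coverage_at,
    first_stage_screenings,
    live_births,
    perinatal_women,
    second_stage_screenings,
    women_treated,
)


def _dec_round(x):
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@pytest.mark.parametrize(
    "population,rate,expected",
    [
        (20_226_000, 35.5, 718_023),
        (20_809_000, 35.5, 738_720),
        (21_413_000, 35.5, 760_162),
        (22_036_000, 35.5, 782_278),
        (22_679_000, 36.0, 816_444),
        (1_000_000, 0, 0),
    ],
)
def test_live_births(population, rate, expected):
    assert live_births(population, rate) == expected


def test_live_births_rejects_negative_inputs():
    with pytest.raises(ValueError):
        live_births(-1, 35.5)


@pytest.mark.parametrize(
    "births,sb,md,expected",
    [
        (718_023, 0.024, 0.003, (735_679, 715_869)),
        (1000, 0, 0, (1000, 1000)),
        (0, 0.024, 0.003, (0, 0)),
    ],
)
def test_perinatal_women(births, sb, md, expected):
    assert perinatal_women(births, sb, md) == expected


def test_perinatal_women_matches_decimal_oracle():
    ante, post = perinatal_women(718_023, 0.024, 0.003)
    assert ante == _dec_round(718_023 / (1 - 0.024))
    assert post == _dec_round(718_023 * (1 - 0.003))


def test_perinatal_women_rejects_certain_stillbirth():
    with pytest.raises(ValueError):
        perinatal_women(1000, 1.0, 0.0)


class TestCoverageAt:
    series = {2022: 0.80, 2024: 0.90, 2026: 1.00}

    def test_tabulated_years(self, defaults):
        assert coverage_at(2024, defaults.cascade.screening_coverage_by_year) == 0.90
        assert coverage_at(2022, defaults.cascade.screening_coverage_by_year) == 0.80

    def test_linear_interpolation(self):
        assert coverage_at(2023, self.series) == pytest.approx(0.85)
        assert coverage_at(2025, self.series) == pytest.approx(0.95)

    def test_constant_interpolation_between_equal_neighbours(self):
        assert coverage_at(2023, {2022: 0.5, 2024: 0.5}) == pytest.approx(0.5)

    def test_out_of_range_is_domain_error(self):
        with pytest.raises(ValueError, match="outside"):
            coverage_at(2030, self.series)


class TestFirstStageScreenings:
    def test_2022_defaults_match_arithmetic_oracle(self, defaults):
        # independent decimal oracle over the same stated inputs
        oracle = _dec_round(
            735_679 * 0.9 * 4 * 0.8 + 715_869 * 0.72 * 1.2 * 0.8
        )
        assert oracle == 2_613_564
        assert first_stage_screenings(735_679, 715_869, defaults, 0.8) == oracle

    def test_zero_coverage(self, defaults):
        assert first_stage_screenings(735_679, 715_869, defaults, 0.0) == 0

    def test_identity_case(self, defaults):
        p = defaults.model_copy(deep=True)
        p.service.screenings_antenatal = 1
        p.service.screenings_postnatal = 1
        p.demographic.clinic_access_antenatal = 1
        p.demographic.clinic_access_postnatal = 1
        assert first_stage_screenings(100, 200, p, 1.0) == 300

    def test_calibration_factor_scales_count(self, defaults):
        base = first_stage_screenings(735_679, 715_869, defaults, 0.8)
        scaled = first_stage_screenings(735_679, 715_869, defaults, 0.8, 0.5)
        assert abs(scaled - base / 2) <= 1


@pytest.mark.parametrize(
    "first,prop,expected",
    [(2_230_858, 0.24, 535_406), (2_438_608, 0.24, 585_266), (10_000, 0, 0)],
)
def test_second_stage_screenings(first, prop, expected):
    assert second_stage_screenings(first, prop) == expected


@pytest.mark.parametrize(
    "second,prop,acc,expected",
    [(535_406, 0.12, 0.95, 61_036), (10_000, 0.2, 0, 0), (100, 1, 1, 100)],
)
def test_women_treated(second, prop, acc, expected):
    assert women_treated(second, prop, acc) == expected


class TestProjection:
    def test_year_on_year_growth_under_defaults(self, default_result):
        """Population, coverage and positivity all rise, so every cascade
        count is non-decreasing over the modelled years."""
        for attr in (
            "live_births",
            "antenatal_women",
            "postnatal_women",
            "first_stage_screenings",
            "second_stage_screenings",
            "second_stage_positives",
            "women_treated",
        ):
            series = [getattr(cy, attr) for cy in default_result.cascade]
            assert series == sorted(series), attr

    def test_cascade_monotone_downstream(self, default_result):
        for cy in default_result.cascade:
            assert cy.second_stage_screenings <= cy.first_stage_screenings
            assert cy.women_treated <= cy.second_stage_positives <= cy.second_stage_screenings

    def test_doubling_population_doubles_counts(self, defaults):
        doubled = defaults.model_copy(deep=True)
        doubled.demographic.population_by_year = {
            y: 2 * v for y, v in defaults.demographic.population_by_year.items()
        }
        base = project_cascade(defaults)
        big = project_cascade(doubled)
        for b, d in zip(base, big):
            for attr in (
                "live_births",
                "first_stage_screenings",
                "second_stage_screenings",
                "women_treated",
            ):
                # each reported quantity re-rounds and feeds the next stage,
                # so the doubled run can drift by a few units
                assert abs(getattr(d, attr) - 2 * getattr(b, attr)) <= 8, attr

    def test_birth_rate_regime_switch(self, defaults):
        births = {cy.year: cy.live_births for cy in project_cascade(defaults)}
        assert births[2022] == 718_023  # 2020-2025 rate
        assert births[2026] == 816_444  # 2025-2030 rate
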