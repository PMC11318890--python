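"""Tabular report bundles and CSV/JSON export.

A report is one table with a row per reported quantity and a column per
modelled year, mirroring the calculator's detailed-results view, plus the
scenario echo, the input fingerprint and a deterministic list of warnings
flagging where the run deviates materially from the published baseline
results (only emitted for quantities with documented discrepancies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._rounding import round_half_up
from .economics import to_usd
from .engine import ProjectionResult
from .reference import KNOWN_DISCREPANT_ROWS, PUBLISHED_BASELINE

__all__ = ["ReportBundle", "build_bundle", "write_report", "plot_summary"]

_WARN_REL_TOL = 0.02


@dataclass(frozen=True)
class ReportBundle:
    """A complete, export-ready results table for one projection."""

    table: pd.DataFrame  # rows: quantities; columns: years
    options: dict[str, float]
    fingerprint: str
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _result_rows(result: ProjectionResult, mwk_per_usd: float) -> dict[str, dict[int, float]]:
    rows: dict[str, dict[int, float]] = {}

    def put(name: str, year: int, value: float) -> None:
        rows.setdefault(name, {})[year] = value

    for cy in result.cascade:
        put("live_births", cy.year, cy.live_births)
        put("antenatal_women", cy.year, cy.antenatal_women)
        put("postnatal_women", cy.year, cy.postnatal_women)
        put("first_stage_screenings", cy.year, cy.first_stage_screenings)
        put("second_stage_screenings", cy.year, cy.second_stage_screenings)
        put("women_treated", cy.year, cy.women_treated)
    for wl in result.workload:
        put("first_stage_days", wl.year, wl.first_stage_days)
        put("second_stage_and_treatment_days", wl.year, wl.second_stage_and_treatment_days)
        put("professionals_fte", wl.year, wl.professionals_fte)
        put("volunteers_fte", wl.year, wl.volunteers_fte)
        put("staff_cost_mwk", wl.year, round_half_up(wl.staff_cost_mwk))
    for tr in result.training:
        put("training_cost_mwk", tr.year, round_half_up(tr.training_cost_mwk))
        put("supervision_cost_mwk", tr.year, round_half_up(tr.supervision_cost_mwk))
    for tv in result.travel:
        put("travel_cost_mwk", tv.year, round_half_up(tv.travel_cost_mwk))
    for bn in result.benefits:
        put("depression_episodes_averted", bn.year, bn.depression_episodes_averted)
        put("mother_dalys", bn.year, round(bn.mother_dalys, 2))
        put("diarrhoea_episodes_averted", bn.year, bn.diarrhoea_episodes_averted)
        put("child_dalys", bn.year, round(bn.child_dalys, 2))
        put("total_dalys", bn.year, bn.total_dalys)
        put("health_benefit_usd", bn.year, round_half_up(bn.health_benefit_usd))
        put(
            "healthcare_savings_usd",
            bn.year,
            round_half_up(to_usd(bn.healthcare_savings_mwk, mwk_per_usd)),
        )
        put("extra_workdays", bn.year, bn.extra_workdays)
        put(
            "productivity_gain_usd",
            bn.year,
            round_half_up(to_usd(bn.productivity_gain_mwk, mwk_per_usd)),
        )
        put("stunting_averted", bn.year, bn.stunting_averted)
    for ec in result.economics:
        put("total_costs_mwk", ec.year, round_half_up(ec.total_costs_mwk))
        put("total_costs_usd", ec.year, ec.total_costs_usd)
        put("total_benefits_usd", ec.year, ec.total_benefits_usd)
        put("net_benefit_usd", ec.year, ec.net_benefit_usd)
        put("npv_usd", ec.year, ec.npv_usd)
        put("roi", ec.year, round(ec.roi, 2) if ec.roi is not None else float("nan"))
    return rows


def _baseline_warnings(rows: dict[str, dict[int, float]]) -> list[str]:
    """One warning per quantity whose computed values deviate more than 2%
    from the published baseline in any year (max deviation reported)."""
    warnings: list[str] = []
    for name, published in PUBLISHED_BASELINE.items():
        computed = rows.get(name, {})
        worst = 0.0
        for year in sorted(set(published) & set(computed)):
            ref = published[year]
            if ref == 0:
                continue
            worst = max(worst, abs(computed[year] - ref) / abs(ref))
        if worst > _WARN_REL_TOL:
            known = " (documented workbook-internal discrepancy)" if name in KNOWN_DISCREPANT_ROWS else ""
            warnings.append(
                f"{name}: deviates up to {worst:.1%} from the published baseline"
                f"{known}; see docs/methods.md"
            )
    return warnings


def build_bundle(result: ProjectionResult, mwk_per_usd: float) -> ReportBundle:
    """Assemble the results table, options echo, fingerprint and warnings."""
    rows = _result_rows(result, mwk_per_usd)
    table = pd.DataFrame(rows).T.reindex(columns=list(result.years))
    table.index.name = "quantity"
    warnings = _baseline_warnings(rows) if _is_default_scenario(result) else []
    return ReportBundle(
        table=table,
        options=result.scenario.model_dump(),
        fingerprint=result.fingerprint,
        warnings=tuple(warnings),
    )


def _is_default_scenario(result: ProjectionResult) -> bool:
    opts = result.scenario
    return (
        opts.salary_first_stage_usd_month == 235
        and opts.salary_psi_usd_month == 40
        and opts.prop_group == 0.5
        and opts.prop_clinic == 0.5
    )


def write_report(bundle: ReportBundle, fmt: str, path: str | Path) -> None:
    """Write the bundle as CSV (rows = quantities, columns = years) or
    JSON (nested year -> quantity). Numbers are locale-independent."""
    if bundle.table.empty or bundle.table.shape[1] == 0:
        raise ValueError("report bundle covers no years; refusing to write an empty file")
    path = Path(path)
    if fmt == "csv":
        bundle.table.to_csv(path)
    elif fmt == "json":
        by_year = {
            str(year): {
                quantity: _jsonify(bundle.table.at[quantity, year])
                for quantity in bundle.table.index
            }
            for year in bundle.table.columns
        }
        payload = {
            "options": bundle.options,
            "fingerprint": bundle.fingerprint,
            "warnings": list(bundle.warnings),
            "results": by_year,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")


def _jsonify(value: float) -> float | int | None:
    if pd.isna(value):
        return None
    if float(value).is_integer():
        return int(value)
    return float(value)


def plot_summary(bundle: ReportBundle, path: str | Path) -> None:
    """Export a net-benefit and ROI chart; failures never propagate to the
    caller's exit status."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = list(bundle.table.columns)
    nb = bundle.table.loc["net_benefit_usd"]
    roi_row = bundle.table.loc["roi"]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.bar(years, nb.values, color="#356f9f")
    ax1.axhline(0, color="black", lw=0.8)
    ax1.set_title("Net benefit (USD, undiscounted)")
    ax1.set_xlabel("Year")
    ax2.plot(years, roi_row.values, marker="o", color="#a14a23")
    ax2.axhline(1.0, color="black", lw=0.8, ls="--")
    ax2.set_title("Return-on-investment ratio")
    ax2.set_xlabel("Year")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
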