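"""Scenario orchestration and one-way sensitivity analysis.

``run_projection`` executes the whole deterministic pipeline — screening
cascade, workforce time, training and supervision, travel, benefits,
headline economics — for one parameter set and scenario.
``one_way_sensitivity`` re-runs it along a grid of values for a single
lever, holding everything else fixed. There is no randomness anywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

from .benefits import BenefitYear, project_benefits
from .cascade import CascadeYear, project_cascade
from .economics import EconomicSummary, project_economics
from .parameters import ParameterSet, ScenarioOptions, validate_options
from .training import TrainingCostYear, project_training
from .travel import TravelCostYear, project_travel
from .workforce import WorkloadYear, project_workload

__all__ = ["ProjectionResult", "SensitivityRow", "run_projection", "one_way_sensitivity"]

_OPTION_LEVERS = (
    "salary_first_stage_usd_month",
    "salary_psi_usd_month",
    "prop_group",
    "prop_clinic",
)


@dataclass(frozen=True)
class ProjectionResult:
    """Complete five-year projection for one scenario."""

    years: tuple[int, ...]
    cascade: tuple[CascadeYear, ...]
    workload: tuple[WorkloadYear, ...]
    training: tuple[TrainingCostYear, ...]
    travel: tuple[TravelCostYear, ...]
    benefits: tuple[BenefitYear, ...]
    economics: tuple[EconomicSummary, ...]
    scenario: ScenarioOptions
    fingerprint: str


@dataclass(frozen=True)
class SensitivityRow:
    """Net benefit and ROI by year for one value of one lever."""

    lever: str
    value: float
    net_benefit_usd: dict[int, int] = field(default_factory=dict)
    roi: dict[int, float | None] = field(default_factory=dict)
    flag_negative_any_year: bool = False


def fingerprint_inputs(params: ParameterSet, options: ScenarioOptions) -> str:
    """Stable hash of the serialized parameter set and options; changes
    whenever any input value changes."""
    payload = json.dumps(
        {"params": params.model_dump(mode="json"), "options": options.model_dump(mode="json")},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def run_projection(
    params: ParameterSet,
    options: ScenarioOptions | None = None,
    calibration_factor: float = 1.0,
) -> ProjectionResult:
    """Run the full deterministic projection.

    Identical inputs produce bit-identical results. Validation errors from
    any stage propagate with their original context.
    """
    options = validate_options(options) if options is not None else ScenarioOptions()
    cascade = project_cascade(params, calibration_factor)
    workload = project_workload(cascade, params, options)
    training = project_training(
        params.years,
        [w.volunteers_fte for w in workload],
        params.training,
        options.salary_psi_usd_month,
        params.econ.mwk_per_usd,
    )
    travel = project_travel(cascade, params, options)
    benefits = project_benefits(cascade, params)
    economics = project_economics(workload, training, travel, benefits, params.econ)
    return ProjectionResult(
        years=tuple(params.years),
        cascade=tuple(cascade),
        workload=tuple(workload),
        training=tuple(training),
        travel=tuple(travel),
        benefits=tuple(benefits),
        economics=tuple(economics),
        scenario=options,
        fingerprint=fingerprint_inputs(params, options),
    )


def _set_parameter_path(params: ParameterSet, path: str, value: Any) -> ParameterSet:
    parts = path.split(".")
    data = params.model_dump()
    node = data
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            raise KeyError(_unknown_lever_message(path))
        node = node[part]
    leaf = parts[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise KeyError(_unknown_lever_message(path))
    if isinstance(node[leaf], dict):
        raise KeyError(f"lever {path!r} addresses a section, not a single numeric value")
    node[leaf] = value
    return ParameterSet.model_validate(data)


def _unknown_lever_message(path: str) -> str:
    return (
        f"unknown lever {path!r}; valid levers are the scenario options "
        f"{', '.join(_OPTION_LEVERS)} or a dotted parameter path such as "
        "'econ.discount_rate'"
    )


def one_way_sensitivity(
    params: ParameterSet,
    options: ScenarioOptions,
    lever: str,
    values: Sequence[float],
) -> list[SensitivityRow]:
    """Re-run the projection for each value of one lever.

    ``lever`` is either one of the four scenario-option names or a dotted
    path into the parameter set (e.g. ``econ.discount_rate``). Rows are
    ordered by lever value.
    """
    rows: list[SensitivityRow] = []
    for value in sorted(values):
        if lever in _OPTION_LEVERS:
            varied_options = options.model_copy(update={lever: value})
            varied_options = validate_options(varied_options)
            varied_params = params
        else:
            varied_params = _set_parameter_path(params, lever, value)
            varied_options = options
        result = run_projection(varied_params, varied_options)
        nb = {e.year: e.net_benefit_usd for e in result.economics}
        rows.append(
            SensitivityRow(
                lever=lever,
                value=value,
                net_benefit_usd=nb,
                roi={e.year: e.roi for e in result.economics},
                flag_negative_any_year=any(v < 0 for v in nb.values()),
            )
        )
    return rows
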