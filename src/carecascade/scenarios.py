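"""Scenario execution, comparison, calibration, and high/low bounds.

The calibration/validation workflow runs named scenario parameter files (no
intervention, current care, high income, per-intervention changes) over one
model definition and compares expected deaths between them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .engine import SubConditionResult, propagate_neonatal, run_subcondition
from .errors import CalibrationError, CascadeError, ValidationError
from .schema import (
    SETTINGS,
    CoverageSpec,
    ModelDefinition,
    ParameterVariant,
    ScenarioParameters,
    copy_params,
)

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "preset_no_intervention",
    "lives_saved",
    "calibrate_incidence",
    "sensitivity_bounds",
    "result_to_frame",
    "lives_saved_to_frame",
]

_POPULATIONS = ("maternal", "fetal", "neonatal")


@dataclass
class ScenarioResult:
    """Deaths and cases by sub-condition and population, with provenance hashes."""

    scenario_id: str
    births: float
    deaths: dict[tuple[str, str], float]  # (subcondition id, population) -> count
    cases: dict[str, float]
    totals: dict[str, float]  # population -> count
    model_hash: str
    params_hash: str
    sub_results: dict[str, SubConditionResult] = field(default_factory=dict)
    bounds: "tuple[ScenarioResult, ScenarioResult] | None" = None  # (low, high)


def run_scenario(model: ModelDefinition, params: ScenarioParameters) -> ScenarioResult:
    """Aggregate the decision tree over every sub-condition.

    Deterministic: identical inputs give bit-identical outputs.  Evaluation
    order is all maternal sub-conditions, then fetal accounting, then neonatal
    sub-conditions (which receive maternal incidence contributions).
    """
    params.validate(model)
    maternal_results = [
        run_subcondition(sub, model, params) for sub in model.maternal_subconditions
    ]
    contributions = propagate_neonatal(maternal_results, model)
    neonatal_results = [
        run_subcondition(sub, model, params, extra_incidence=contributions.get(sub.id))
        for sub in model.neonatal_subconditions
    ]

    adj = params.mortality_adjustment
    deaths: dict[tuple[str, str], float] = {}
    cases: dict[str, float] = {}
    sub_results: dict[str, SubConditionResult] = {}
    for res in maternal_results:
        deaths[(res.subcondition_id, "maternal")] = res.maternal_deaths * adj
        deaths[(res.subcondition_id, "fetal")] = res.fetal_deaths * adj
        cases[res.subcondition_id] = res.cases
        sub_results[res.subcondition_id] = res
    for res in neonatal_results:
        deaths[(res.subcondition_id, "neonatal")] = res.neonatal_deaths * adj
        cases[res.subcondition_id] = res.cases
        sub_results[res.subcondition_id] = res
    totals = {
        pop: sum(v for (_, p), v in deaths.items() if p == pop) for pop in _POPULATIONS
    }
    return ScenarioResult(
        scenario_id=params.scenario_id,
        births=params.births,
        deaths=deaths,
        cases=cases,
        totals=totals,
        model_hash=model.content_hash(),
        params_hash=params.content_hash(),
        sub_results=sub_results,
    )


def preset_no_intervention(params: ScenarioParameters) -> ScenarioParameters:
    """Copy of ``params`` with every penetration and utilization set to zero.

    Reproduces the historical no-intervention limit: deaths equal
    births x incidence x untreated CFR.  Idempotent.
    """
    out = copy_params(params)
    out.scenario_id = (
        params.scenario_id
        if params.scenario_id.endswith("::no_intervention")
        else f"{params.scenario_id}::no_intervention"
    )
    zero = {s: CoverageSpec(0.0, 0.0) for s in SETTINGS}
    out.coverage = {key: dict(zero) for key in params.coverage}
    out.coverage_overrides = {key: dict(zero) for key in params.coverage}
    return out


def lives_saved(
    reference: ScenarioResult, comparison: ScenarioResult
) -> dict[str, object]:
    """Reference deaths minus comparison deaths, per population and sub-condition.

    Positive numbers mean the comparison scenario saves lives.  Both results
    must come from the same model definition and cohort size.
    """
    if reference.model_hash != comparison.model_hash:
        raise CascadeError(
            "cannot compare results from different model definitions "
            f"({reference.model_hash} vs {comparison.model_hash})"
        )
    if reference.births != comparison.births:
        raise CascadeError(
            f"cannot compare cohorts of different size "
            f"({reference.births} vs {comparison.births})"
        )
    by_key = {
        key: reference.deaths.get(key, 0.0) - comparison.deaths.get(key, 0.0)
        for key in set(reference.deaths) | set(comparison.deaths)
    }
    by_population = {
        pop: reference.totals.get(pop, 0.0) - comparison.totals.get(pop, 0.0)
        for pop in _POPULATIONS
    }
    return {"by_population": by_population, "by_subcondition": by_key}


def calibrate_incidence(target_mortality_rate: float, untreated_cfr: float) -> float:
    """Un-prevented incidence that makes the no-intervention run hit the target.

    Inverts deaths-per-pregnancy = incidence x untreated CFR.
    """
    if not 0.0 < untreated_cfr <= 1.0:
        raise CalibrationError(f"untreated CFR must be in (0, 1], got {untreated_cfr}")
    if not 0.0 <= target_mortality_rate <= 1.0:
        raise CalibrationError(
            f"target mortality must be a rate in [0, 1], got {target_mortality_rate}"
        )
    if target_mortality_rate > untreated_cfr:
        raise CalibrationError(
            f"infeasible calibration: target mortality {target_mortality_rate} "
            f"exceeds untreated CFR {untreated_cfr} (implied incidence > 1)"
        )
    return target_mortality_rate / untreated_cfr


def _apply_variant(
    model: ModelDefinition,
    params: ScenarioParameters,
    variant: ParameterVariant,
    label: str,
) -> tuple[ModelDefinition, ScenarioParameters]:
    """Materialize a bound variant as a (model, params) pair."""
    subs = []
    for sub in model.sub_conditions:
        overrides = variant.rate_overrides.get(sub.id)
        subs.append(dataclasses.replace(sub, **overrides) if overrides else sub)
    model_v = ModelDefinition(
        sub_conditions=subs,
        interventions=model.interventions,
        transfers=model.transfers,
        schema_version=model.schema_version,
    )
    model_v.validate()
    params_v = copy_params(params)
    params_v.scenario_id = f"{params.scenario_id}::{label}"
    params_v.bounds = None
    for iv in model.interventions:
        for ref in (iv.id, iv.key):
            if ref in variant.coverage_overrides:
                params_v.coverage.setdefault(iv.key, {}).update(
                    variant.coverage_overrides[ref]
                )
    return model_v, params_v


def sensitivity_bounds(
    model: ModelDefinition, params: ScenarioParameters
) -> ScenarioResult:
    """Run the central scenario plus its low and high parameter variants.

    Bounds are two full deterministic runs, not interval arithmetic.  The low
    and high results are attached to the central result.
    """
    if params.bounds is None:
        raise ValidationError("bounds", "scenario declares no low/high bounds")
    central = run_scenario(model, params)
    low_model, low_params = _apply_variant(model, params, params.bounds.low, "low")
    high_model, high_params = _apply_variant(model, params, params.bounds.high, "high")
    central.bounds = (
        run_scenario(low_model, low_params),
        run_scenario(high_model, high_params),
    )
    return central


def result_to_frame(result: ScenarioResult) -> pd.DataFrame:
    """Tidy results table: scenario, subcondition, population, deaths, cases, low, high."""
    low, high = (result.bounds if result.bounds is not None else (None, None))
    rows = []
    for (sub_id, pop), count in sorted(result.deaths.items()):
        rows.append(
            {
                "scenario_id": result.scenario_id,
                "subcondition": sub_id,
                "population": pop,
                "deaths": count,
                "cases": result.cases.get(sub_id, 0.0),
                "low": low.deaths.get((sub_id, pop)) if low is not None else None,
                "high": high.deaths.get((sub_id, pop)) if high is not None else None,
            }
        )
    for pop in _POPULATIONS:
        rows.append(
            {
                "scenario_id": result.scenario_id,
                "subcondition": "__total__",
                "population": pop,
                "deaths": result.totals[pop],
                "cases": sum(result.cases.values()),
                "low": low.totals.get(pop) if low is not None else None,
                "high": high.totals.get(pop) if high is not None else None,
            }
        )
    return pd.DataFrame(rows)


def lives_saved_to_frame(
    saved: Mapping[str, object],
    reference_id: str,
    comparison_id: str,
) -> pd.DataFrame:
    """Summary table of lives saved between two named scenarios."""
    rows = []
    for (sub_id, pop), delta in sorted(saved["by_subcondition"].items()):  # type: ignore[union-attr]
        rows.append(
            {
                "reference": reference_id,
                "comparison": comparison_id,
                "subcondition": sub_id,
                "population": pop,
                "lives_saved": delta,
            }
        )
    for pop, delta in sorted(saved["by_population"].items()):  # type: ignore[union-attr]
        rows.append(
            {
                "reference": reference_id,
                "comparison": comparison_id,
                "subcondition": "__total__",
                "population": pop,
                "lives_saved": delta,
            }
        )
    return pd.DataFrame(rows)
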