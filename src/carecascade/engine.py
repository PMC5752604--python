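"""Deterministic expected-value propagation of the pregnancy cohort.

Each sub-condition runs, per care setting, through the decision tree

    incidence -> prevention -> diagnosis -> transfer -> treatment -> mortality

on expected-count masses.  No rounding happens until report rendering; mass is
conserved at every split and the full strata trace is recorded for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from . import algebra
from .algebra import AppliedIntervention, Stage
from .errors import ConfigurationError
from .schema import (
    SETTINGS,
    InterventionKind,
    ModelDefinition,
    PopulationType,
    ScenarioParameters,
    Setting,
    SubConditionSpec,
    TransferRule,
    effective_transfers_for,
)

__all__ = [
    "CohortStratum",
    "SubConditionResult",
    "initial_strata",
    "apply_prevention",
    "apply_diagnosis",
    "apply_transfer",
    "apply_treatment",
    "compute_mortality",
    "propagate_neonatal",
    "run_subcondition",
    "trace_to_frame",
]

_MASS_RTOL = 1e-9

_KIND_STAGE = {
    InterventionKind.PREVENTIVE: Stage.PREVENTION,
    InterventionKind.DIAGNOSTIC: Stage.DIAGNOSIS,
    InterventionKind.TREATMENT: Stage.TREATMENT,
}


@dataclass(frozen=True)
class CohortStratum:
    """An expected-count mass of pregnancies with a shared pathway label.

    ``fetal_survival_factor`` / ``neonatal_survival_factor`` record the exact
    expected per-treatment benefit multipliers for successfully treated mass
    (1.0 elsewhere).
    """

    mass: float
    setting: Setting
    condition_positive: bool | None = None
    diagnosed: bool | None = None
    treated_successfully: bool | None = None
    fetal_survival_factor: float = 1.0
    neonatal_survival_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"stratum mass must be >= 0, got {self.mass}")
        if self.diagnosed and not self.condition_positive:
            raise ValueError("diagnosed strata must be condition-positive")


@dataclass
class SubConditionResult:
    """Outcome of one sub-condition's decision tree over the whole cohort."""

    subcondition_id: str
    population: PopulationType
    cases: float
    maternal_deaths: float
    fetal_deaths: float
    neonatal_deaths: float
    neonatal_incidence_contributions: dict[str, float]
    contributions_by_setting: dict[str, dict[Setting, float]]
    interventions_administered: dict[str, float]
    strata_trace: list[tuple[str, CohortStratum]] = field(default_factory=list)

    @property
    def deaths(self) -> float:
        """Deaths in this sub-condition's own population."""
        if self.population is PopulationType.NEONATAL:
            return self.neonatal_deaths
        return self.maternal_deaths


# -- elementary tree operations ---------------------------------------------


def initial_strata(params: ScenarioParameters) -> list[CohortStratum]:
    """One stratum per setting: mass = births x setting fraction."""
    return [
        CohortStratum(
            mass=params.births * params.setting_distribution.get(s, 0.0),
            setting=s,
        )
        for s in SETTINGS
    ]


def apply_prevention(
    stratum: CohortStratum,
    sub: SubConditionSpec,
    prevention_success: float,
) -> tuple[CohortStratum, CohortStratum]:
    """Split a stratum into condition-positive and condition-negative mass.

    Positive mass is the un-prevented incidence thinned by the prevention
    success; prevented individuals carry zero mortality risk from this
    sub-condition.
    """
    positive_mass = stratum.mass * sub.unprevented_incidence * (1.0 - prevention_success)
    positive = replace(stratum, mass=positive_mass, condition_positive=True)
    negative = replace(stratum, mass=stratum.mass - positive_mass, condition_positive=False)
    return positive, negative


def apply_diagnosis(
    positive: CohortStratum, diagnosis_success: float
) -> tuple[CohortStratum, CohortStratum]:
    """Split condition-positive mass by diagnostic success.

    Undiagnosed mass can receive neither treatment nor transfer; condition
    negatives are never diagnosed here (false positives receive no benefit).
    """
    if not positive.condition_positive:
        raise ConfigurationError("apply_diagnosis requires a condition-positive stratum")
    diagnosed = replace(positive, mass=positive.mass * diagnosis_success, diagnosed=True)
    undiagnosed = replace(positive, mass=positive.mass - diagnosed.mass, diagnosed=False)
    return diagnosed, undiagnosed


def apply_transfer(
    diagnosed: CohortStratum, rules: Sequence[TransferRule]
) -> list[CohortStratum]:
    """Split diagnosed mass across destination settings; movers adopt the
    destination.  At most one transfer per pregnancy per sub-condition."""
    total_p = sum(r.probability for r in rules)
    if total_p > 1.0 + 1e-12:
        raise ConfigurationError(
            f"transfer probabilities from {diagnosed.setting.value} sum to {total_p} > 1"
        )
    out: list[CohortStratum] = []
    moved = 0.0
    for rule in rules:
        if rule.from_setting is not diagnosed.setting:
            raise ConfigurationError("transfer rule does not match stratum setting")
        mass = diagnosed.mass * rule.probability
        moved += mass
        out.append(replace(diagnosed, mass=mass, setting=rule.to_setting))
    # rounding can leave a ~1e-13 negative residue when probabilities sum to 1
    out.append(replace(diagnosed, mass=max(0.0, diagnosed.mass - moved)))
    return out


def apply_treatment(
    diagnosed: CohortStratum, treatment_success: float
) -> tuple[CohortStratum, CohortStratum]:
    """Split diagnosed mass into successfully treated and failed."""
    if not diagnosed.diagnosed:
        raise ConfigurationError("apply_treatment requires a diagnosed stratum")
    success = replace(
        diagnosed, mass=diagnosed.mass * treatment_success, treated_successfully=True
    )
    failure = replace(
        diagnosed, mass=diagnosed.mass - success.mass, treated_successfully=False
    )
    return success, failure


def compute_mortality(
    strata: Sequence[CohortStratum], sub: SubConditionSpec
) -> tuple[float, float]:
    """Expected deaths (sub-condition's own population, fetal) over terminal strata.

    Untreated / undiagnosed / failed mass dies at the untreated CFR; treated
    mass at the treated CFR.  Fetal rates follow the same stratification with
    the treated stratum's fetal rate further scaled by its exact
    per-treatment survival factor.
    """
    deaths = 0.0
    fetal = 0.0
    for stratum in strata:
        if not stratum.condition_positive:
            continue
        treated = bool(stratum.treated_successfully)
        cfr = sub.treated_cfr if treated else sub.untreated_cfr
        deaths += stratum.mass * cfr
        if sub.fetal_death_rate_untreated is not None:
            if treated:
                fetal += (
                    stratum.mass
                    * sub.fetal_death_rate_treated
                    * stratum.fetal_survival_factor
                )
            else:
                fetal += stratum.mass * sub.fetal_death_rate_untreated
    return deaths, fetal


# -- stage composition helpers ----------------------------------------------


def _applied_stage(
    model: ModelDefinition,
    params: ScenarioParameters,
    sub_id: str,
    kind: InterventionKind,
    setting: Setting,
) -> tuple[list[AppliedIntervention], list[list[AppliedIntervention]]]:
    """Build AppliedInterventions for one (sub-condition, stage, setting)."""
    layers: list[AppliedIntervention] = []
    lines: list[tuple[int, AppliedIntervention]] = []
    for iv in model.interventions_for(sub_id, kind):
        cov = params.coverage_at(iv.key, setting)
        receive = algebra.coverage(cov.penetration, cov.utilization)
        applied = AppliedIntervention(
            intervention_id=iv.key,
            setting=setting,
            receive_probability=receive,
            success_probability=algebra.success(receive, iv.efficacy),
            stage=_KIND_STAGE[kind],
        )
        if iv.composition.mode == "line":
            lines.append((iv.composition.order, applied))
        else:
            layers.append(applied)
    lines.sort(key=lambda pair: pair[0])
    line_groups = [[ai for _, ai in lines]] if lines else []
    return layers, line_groups


def _stage_success(
    model: ModelDefinition,
    params: ScenarioParameters,
    sub_id: str,
    kind: InterventionKind,
    setting: Setting,
) -> float:
    layers, groups = _applied_stage(model, params, sub_id, kind, setting)
    return algebra.combine_stage(layers, groups)


@dataclass(frozen=True)
class _TreatmentEffect:
    """Summary of the enumerated treatment-outcome distribution at one setting."""

    success_probability: float
    fetal_survival_factor: float  # E[prod(1 - fetal_eff_i) | success]
    neonatal_survival_factor: float  # E[prod(1 - neonatal_eff_i) | success]
    expected_administered: dict[str, float]  # per diagnosed person


def _treatment_effect(
    model: ModelDefinition,
    params: ScenarioParameters,
    sub_id: str,
    setting: Setting,
) -> _TreatmentEffect:
    layers, groups = _applied_stage(
        model, params, sub_id, InterventionKind.TREATMENT, setting
    )
    outcomes = algebra.enumerate_stage(layers, groups)
    fetal_eff: dict[str, float] = {}
    neo_eff: dict[str, float] = {}
    for ai in [*layers, *(ai for g in groups for ai in g)]:
        spec = model.intervention_by_key(ai.intervention_id)
        fetal_eff[ai.intervention_id] = spec.fetal_efficacy or 0.0
        neo_eff[ai.intervention_id] = spec.neonatal_efficacy or 0.0
    p_success = 0.0
    fetal_num = 0.0
    neo_num = 0.0
    administered: dict[str, float] = {k: 0.0 for k in fetal_eff}
    for out in outcomes:
        for key in out.administered:
            administered[key] += out.probability
        if not out.succeeded:
            continue
        p_success += out.probability
        ff = 1.0
        nf = 1.0
        for key in out.succeeded:
            ff *= 1.0 - fetal_eff[key]
            nf *= 1.0 - neo_eff[key]
        fetal_num += out.probability * ff
        neo_num += out.probability * nf
    return _TreatmentEffect(
        success_probability=p_success,
        fetal_survival_factor=fetal_num / p_success if p_success > 0 else 1.0,
        neonatal_survival_factor=neo_num / p_success if p_success > 0 else 1.0,
        expected_administered=administered,
    )


def _expected_administered(
    model: ModelDefinition,
    params: ScenarioParameters,
    sub_id: str,
    kind: InterventionKind,
    setting: Setting,
) -> dict[str, float]:
    """Per-eligible-person probability of receiving each intervention."""
    layers, groups = _applied_stage(model, params, sub_id, kind, setting)
    tally: dict[str, float] = {}
    for out in algebra.enumerate_stage(layers, groups):
        for key in out.administered:
            tally[key] = tally.get(key, 0.0) + out.probability
    return tally


# -- full sub-condition tree -------------------------------------------------


def _assert_conserved(parent: float, children: Sequence[float], step: str) -> None:
    total = sum(children)
    tol = _MASS_RTOL * max(1.0, abs(parent))
    if abs(total - parent) > tol:
        raise ConfigurationError(
            f"mass not conserved at {step}: parent {parent} vs children {total}"
        )


def run_subcondition(
    sub: SubConditionSpec,
    model: ModelDefinition,
    params: ScenarioParameters,
    extra_incidence: Mapping[Setting, float] | None = None,
) -> SubConditionResult:
    """Propagate the cohort through one sub-condition's full decision tree.

    ``extra_incidence`` carries incident case mass contributed by maternal
    sub-conditions (neonatal runs only); it passes through prevention,
    diagnosis, transfer and treatment like background incidence.
    """
    _check_pathway_constraints(sub, model, params)
    extra = dict(extra_incidence or {})
    trace: list[tuple[str, CohortStratum]] = []
    administered: dict[str, float] = {}
    terminal: list[CohortStratum] = []
    cases = 0.0
    contributions: dict[str, dict[Setting, float]] = {
        neo_id: {s: 0.0 for s in SETTINGS} for neo_id in sub.neonatal_links
    }

    for base in initial_strata(params):
        setting = base.setting
        extra_mass = extra.get(setting, 0.0)
        entry = replace(base, mass=base.mass + extra_mass)
        trace.append(("initial", entry))

        p_prev = _stage_success(model, params, sub.id, InterventionKind.PREVENTIVE, setting)
        # background mass runs through the spec'd split; contributed mass is
        # already incident, so only the prevention thinning applies to it
        positive_base, negative = apply_prevention(base, sub, p_prev)
        positive = replace(
            positive_base, mass=positive_base.mass + extra_mass * (1.0 - p_prev)
        )
        negative = replace(
            negative,
            mass=max(0.0, entry.mass - positive.mass),
            condition_positive=False,
        )
        _assert_conserved(entry.mass, [positive.mass, negative.mass], "prevention")
        trace.append(("prevention:positive", positive))
        trace.append(("prevention:negative", negative))
        cases += positive.mass
        for key, frac in _expected_administered(
            model, params, sub.id, InterventionKind.PREVENTIVE, setting
        ).items():
            administered[key] = administered.get(key, 0.0) + entry.mass * frac

        p_diag = _stage_success(model, params, sub.id, InterventionKind.DIAGNOSTIC, setting)
        diagnosed, undiagnosed = apply_diagnosis(positive, p_diag)
        _assert_conserved(positive.mass, [diagnosed.mass, undiagnosed.mass], "diagnosis")
        trace.append(("diagnosis:diagnosed", diagnosed))
        trace.append(("diagnosis:undiagnosed", undiagnosed))
        terminal.append(undiagnosed)
        for key, frac in _expected_administered(
            model, params, sub.id, InterventionKind.DIAGNOSTIC, setting
        ).items():
            administered[key] = administered.get(key, 0.0) + positive.mass * frac

        rules = effective_transfers_for(model, params, sub.id, setting)
        post_transfer = apply_transfer(diagnosed, rules)
        _assert_conserved(diagnosed.mass, [s.mass for s in post_transfer], "transfer")
        for stratum in post_transfer:
            trace.append((f"transfer:{stratum.setting.value}", stratum))

        terminal_here: list[CohortStratum] = [undiagnosed]
        for stratum in post_transfer:
            effect = _treatment_effect(model, params, sub.id, stratum.setting)
            treated, failed = apply_treatment(stratum, effect.success_probability)
            treated = replace(
                treated,
                fetal_survival_factor=effect.fetal_survival_factor,
                neonatal_survival_factor=effect.neonatal_survival_factor,
            )
            _assert_conserved(stratum.mass, [treated.mass, failed.mass], "treatment")
            trace.append(("treatment:success", treated))
            trace.append(("treatment:failure", failed))
            terminal.extend([treated, failed])
            terminal_here.extend([treated, failed])
            for key, frac in effect.expected_administered.items():
                administered[key] = administered.get(key, 0.0) + stratum.mass * frac

        # linked neonatal cases stay attributed to the maternal origin setting:
        # the mother may transfer for her own care, but the cohort's neonatal
        # care location is set by where the pregnancy receives care
        for stratum in terminal_here:
            for neo_id, link in sub.neonatal_links.items():
                if stratum.treated_successfully:
                    rate = link.treated * stratum.neonatal_survival_factor
                else:
                    rate = link.untreated
                contributions[neo_id][setting] += stratum.mass * rate

    deaths, fetal_deaths = compute_mortality(terminal, sub)

    return SubConditionResult(
        subcondition_id=sub.id,
        population=sub.population,
        cases=cases,
        maternal_deaths=deaths if sub.population is PopulationType.MATERNAL else 0.0,
        fetal_deaths=fetal_deaths,
        neonatal_deaths=deaths if sub.population is PopulationType.NEONATAL else 0.0,
        neonatal_incidence_contributions={
            neo_id: sum(by_setting.values())
            for neo_id, by_setting in contributions.items()
        },
        contributions_by_setting=contributions,
        interventions_administered=administered,
        strata_trace=trace,
    )


def _check_pathway_constraints(
    sub: SubConditionSpec, model: ModelDefinition, params: ScenarioParameters
) -> None:
    """Raise if the sub-condition's pathway violates usage constraints."""
    pathway: list[AppliedIntervention] = []
    for kind in InterventionKind:
        layers, groups = _applied_stage(
            model, params, sub.id, kind, Setting.HOSPITAL
        )
        pathway.extend(layers)
        for group in groups:
            pathway.extend(group)
    violations = algebra.check_usage_constraints(pathway, model)
    if violations:
        raise ConfigurationError(
            f"usage constraint violations for {sub.id!r}: "
            + "; ".join(f"{v.intervention_id} x{v.count}" for v in violations)
        )


def propagate_neonatal(
    maternal_results: Sequence[SubConditionResult],
    model: ModelDefinition,
) -> dict[str, dict[Setting, float]]:
    """Accumulate neonatal incident-case mass contributed by maternal strata.

    Returns a per-neonatal-sub-condition mapping of contributed mass by the
    maternal stratum's (post-transfer) setting.  Neonatal results never feed
    back into maternal or fetal deaths.
    """
    neonatal_ids = {s.id for s in model.neonatal_subconditions}
    out: dict[str, dict[Setting, float]] = {
        neo_id: {s: 0.0 for s in SETTINGS} for neo_id in neonatal_ids
    }
    for result in maternal_results:
        for neo_id, by_setting in result.contributions_by_setting.items():
            if neo_id not in neonatal_ids:
                raise ConfigurationError(
                    f"maternal sub-condition {result.subcondition_id!r} links to "
                    f"unknown neonatal sub-condition {neo_id!r}"
                )
            for setting, mass in by_setting.items():
                out[neo_id][setting] += mass
    return out


def trace_to_frame(result: SubConditionResult) -> pd.DataFrame:
    """Tidy audit trail: one row per stratum per step."""
    rows = []
    for step, stratum in result.strata_trace:
        rows.append(
            {
                "subcondition": result.subcondition_id,
                "step": step,
                "setting": stratum.setting.value,
                "condition_positive": stratum.condition_positive,
                "diagnosed": stratum.diagnosed,
                "treated_successfully": stratum.treated_successfully,
                "mass": stratum.mass,
            }
        )
    return pd.DataFrame(rows)
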