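"""Shared fixtures and independent brute-force oracles.

The oracles enumerate joint Bernoulli outcomes or simulate individuals event
by event; they share no code with the package's probability composition.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pytest

from carecascade import fixtures
from carecascade.schema import (
    CoverageSpec,
    InterventionKind,
    InterventionSpec,
    ModelDefinition,
    PopulationType,
    ScenarioParameters,
    Setting,
    SubConditionSpec,
    resolve_coverage,
)

FIXTURES_DIR = Path(__file__).resolve().parents[1] / "fixtures"


@pytest.fixture(scope="session")
def model():
    return fixtures.default_model()


@pytest.fixture()
def params(model):
    return fixtures.default_scenario(model)


# -- oracles -----------------------------------------------------------------


def brute_force_layers(successes: list[float]) -> float:
    """P(at least one success) by enumerating all joint Bernoulli outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(successes)):
        p = 1.0
        for bit, s in zip(outcome, successes):
            p *= s if bit else (1.0 - s)
        if any(outcome):
            total += p
    return total


def brute_force_lines(lines: list[tuple[float, float]]):
    """Enumerate receive/success draws, then walk the cascade per outcome."""
    n = len(lines)
    overall = 0.0
    administered = [0.0] * n
    for recv in itertools.product([0, 1], repeat=n):
        for succ in itertools.product([0, 1], repeat=n):
            p = 1.0
            for k, (c, e) in enumerate(lines):
                p *= c if recv[k] else (1.0 - c)
                p *= e if succ[k] else (1.0 - e)
            worked = False
            given = []
            for k in range(n):
                if not recv[k]:
                    break
                given.append(k)
                if succ[k]:
                    worked = True
                    break
            for k in given:
                administered[k] += p
            if worked:
                overall += p
    return overall, administered


def simulate_stage_individuals(
    rng: np.random.Generator,
    layers: list[tuple[float, float]],
    line_groups: list[list[tuple[float, float]]],
    n: int,
) -> np.ndarray:
    """Per-individual event sequencing for one stage; returns success flags."""
    success = np.zeros(n, dtype=bool)
    for c, e in layers:
        received = rng.random(n) < c
        success |= received & (rng.random(n) < e)
    for group in line_groups:
        eligible = np.ones(n, dtype=bool)
        for c, e in group:
            received = eligible & (rng.random(n) < c)
            ok = received & (rng.random(n) < e)
            success |= ok
            eligible = received & ~ok
    return success


# -- tiny-model builder ------------------------------------------------------


def make_simple_model(
    incidence: float = 0.1,
    untreated_cfr: float = 0.02,
    treated_cfr: float = 0.0,
    preventive_efficacy: float | None = None,
    diagnostic_efficacy: float | None = None,
    treatment_efficacy: float | None = None,
    coverage: tuple[float, float] = (1.0, 1.0),
) -> ModelDefinition:
    """One maternal sub-condition with optional single-layer stage interventions."""
    sub = SubConditionSpec(
        id="sub",
        condition_id="cond",
        population=PopulationType.MATERNAL,
        unprevented_incidence=incidence,
        untreated_cfr=untreated_cfr,
        treated_cfr=treated_cfr,
    )
    cov = {s: CoverageSpec(*coverage) for s in Setting}
    interventions = []
    if preventive_efficacy is not None:
        interventions.append(
            InterventionSpec(
                id="prevent", kind=InterventionKind.PREVENTIVE,
                target_subcondition_ids=frozenset({"sub"}),
                efficacy=preventive_efficacy, coverage=dict(cov),
            )
        )
    if diagnostic_efficacy is not None:
        interventions.append(
            InterventionSpec(
                id="diagnose", kind=InterventionKind.DIAGNOSTIC,
                target_subcondition_ids=frozenset({"sub"}),
                efficacy=diagnostic_efficacy, coverage=dict(cov),
            )
        )
    if treatment_efficacy is not None:
        interventions.append(
            InterventionSpec(
                id="treat", kind=InterventionKind.TREATMENT,
                target_subcondition_ids=frozenset({"sub"}),
                efficacy=treatment_efficacy, coverage=dict(cov),
            )
        )
    m = ModelDefinition(sub_conditions=[sub], interventions=interventions, transfers=[])
    m.validate()
    return m


def make_simple_params(
    model: ModelDefinition, births: float = 100_000.0
) -> ScenarioParameters:
    p = ScenarioParameters(
        scenario_id="simple",
        births=births,
        setting_distribution={
            Setting.HOME: 0.5, Setting.CLINIC: 0.3, Setting.HOSPITAL: 0.2
        },
        coverage=resolve_coverage(model, {}),
    )
    p.validate(model)
    return p
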