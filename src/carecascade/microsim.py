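"""Seeded individual-level Monte Carlo oracle for the analytic engine.

Re-implements the decision tree as explicit per-individual Bernoulli event
sequencing (vectorized over individuals), sharing no probability-composition
code with :mod:`carecascade.algebra` or :mod:`carecascade.engine`.  Exists
purely for verification — the production model is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scenarios import ScenarioResult
from .schema import (
    SETTINGS,
    InterventionKind,
    ModelDefinition,
    ScenarioParameters,
    SubConditionSpec,
    effective_transfers_for,
)

__all__ = ["SimulationConfig", "simulate", "compare", "ComparisonRow"]

_INDEX_BY_SETTING = {s: i for i, s in enumerate(SETTINGS)}


@dataclass
class SimulationConfig:
    n_individuals: int
    seed: int
    model: ModelDefinition
    params: ScenarioParameters
    event_log_limit: int = 0  # rows of per-individual event log to retain

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")


@dataclass
class _Stream:
    """One stream of potential cases: onset flags plus each individual's setting."""

    incident: np.ndarray  # bool
    settings: np.ndarray  # int index into SETTINGS
    source: str


@dataclass
class _SubTally:
    cases: int = 0
    deaths: int = 0
    fetal_deaths: int = 0
    link_streams: dict[str, list[_Stream]] = field(default_factory=dict)


def _coverage_lookup(
    params: ScenarioParameters, key: str
) -> np.ndarray:
    """Receive probability (penetration x utilization) indexed by setting."""
    out = np.empty(len(SETTINGS))
    for i, s in enumerate(SETTINGS):
        cov = params.coverage_at(key, s)
        out[i] = cov.penetration * cov.utilization
    return out


def _simulate_stage(
    rng: np.random.Generator,
    model: ModelDefinition,
    params: ScenarioParameters,
    sub_id: str,
    kind: InterventionKind,
    settings: np.ndarray,
    eligible: np.ndarray,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw one stage for every individual; returns (any-success, success-by-key).

    Layers draw receipt and success independently; line k is only attempted by
    individuals who received and failed line k-1.
    """
    n = settings.shape[0]
    any_success = np.zeros(n, dtype=bool)
    succeeded: dict[str, np.ndarray] = {}
    layer_specs = []
    line_specs = []
    for iv in model.interventions_for(sub_id, kind):
        if iv.composition.mode == "line":
            line_specs.append((iv.composition.order, iv))
        else:
            layer_specs.append(iv)
    for iv in layer_specs:
        recv_p = _coverage_lookup(params, iv.key)[settings]
        received = eligible & (rng.random(n) < recv_p)
        ok = received & (rng.random(n) < iv.efficacy)
        succeeded[iv.key] = ok
        any_success |= ok
    still_eligible = eligible.copy()
    for _, iv in sorted(line_specs, key=lambda pair: pair[0]):
        recv_p = _coverage_lookup(params, iv.key)[settings]
        received = still_eligible & (rng.random(n) < recv_p)
        ok = received & (rng.random(n) < iv.efficacy)
        succeeded[iv.key] = ok
        any_success |= ok
        still_eligible = received & ~ok
    return any_success, succeeded


def _simulate_transfers(
    rng: np.random.Generator,
    model: ModelDefinition,
    params: ScenarioParameters,
    sub_id: str,
    settings: np.ndarray,
    diagnosed: np.ndarray,
) -> np.ndarray:
    """Draw at most one upward transfer per diagnosed individual."""
    new_settings = settings.copy()
    n = settings.shape[0]
    for setting in SETTINGS:
        rules = effective_transfers_for(model, params, sub_id, setting)
        if not rules:
            continue
        u = rng.random(n)
        mask = diagnosed & (settings == _INDEX_BY_SETTING[setting])
        lo = 0.0
        for rule in rules:
            hi = lo + rule.probability
            sel = mask & (u >= lo) & (u < hi)
            new_settings[sel] = _INDEX_BY_SETTING[rule.to_setting]
            lo = hi
    return new_settings


def _simulate_subcondition(
    rng: np.random.Generator,
    model: ModelDefinition,
    params: ScenarioParameters,
    sub: SubConditionSpec,
    streams: Sequence[_Stream],
) -> _SubTally:
    tally = _SubTally(link_streams={neo_id: [] for neo_id in sub.neonatal_links})
    treatments = model.interventions_for(sub.id, InterventionKind.TREATMENT)
    for stream in streams:
        n = stream.incident.shape[0]
        settings = stream.settings

        prevented, _ = _simulate_stage(
            rng, model, params, sub.id, InterventionKind.PREVENTIVE,
            settings, np.ones(n, dtype=bool),
        )
        positive = stream.incident & ~prevented
        tally.cases += int(positive.sum())

        diag_success, _ = _simulate_stage(
            rng, model, params, sub.id, InterventionKind.DIAGNOSTIC,
            settings, np.ones(n, dtype=bool),
        )
        diagnosed = positive & diag_success

        care_settings = _simulate_transfers(
            rng, model, params, sub.id, settings, diagnosed
        )

        treated, succeeded = _simulate_stage(
            rng, model, params, sub.id, InterventionKind.TREATMENT,
            care_settings, diagnosed,
        )
        treated &= diagnosed

        cfr = np.where(treated, sub.treated_cfr, sub.untreated_cfr)
        tally.deaths += int((positive & (rng.random(n) < cfr)).sum())

        if sub.fetal_death_rate_untreated is not None:
            survival = np.ones(n)
            for iv in treatments:
                if iv.fetal_efficacy:
                    survival[succeeded[iv.key]] *= 1.0 - iv.fetal_efficacy
            rate = np.where(
                treated,
                sub.fetal_death_rate_treated * survival,
                sub.fetal_death_rate_untreated,
            )
            tally.fetal_deaths += int((positive & (rng.random(n) < rate)).sum())

        for neo_id, link in sub.neonatal_links.items():
            survival = np.ones(n)
            for iv in treatments:
                if iv.neonatal_efficacy:
                    survival[succeeded[iv.key]] *= 1.0 - iv.neonatal_efficacy
            rate = np.where(treated, link.treated * survival, link.untreated)
            onset = positive & (rng.random(n) < rate)
            # linked neonates stay attributed to the pregnancy's origin setting
            tally.link_streams[neo_id].append(
                _Stream(incident=onset, settings=settings,
                        source=f"{sub.id}->{neo_id}")
            )
    return tally


def simulate(config: SimulationConfig) -> ScenarioResult:
    """Run the full scenario as a seeded Monte Carlo of ``n_individuals``.

    Deaths and cases are raw simulated counts (``births`` on the result equals
    ``n_individuals``); divide by n for rates.  Requires
    ``mortality_adjustment == 1`` since adjusted counts are no longer binomial.
    """
    model, params = config.model, config.params
    params.validate(model)
    if params.mortality_adjustment != 1.0:
        raise ConfigurationError(
            "microsimulation requires mortality_adjustment == 1"
        )
    n = config.n_individuals

    rng_settings = np.random.default_rng([config.seed, 0])
    dist = np.array([params.setting_distribution.get(s, 0.0) for s in SETTINGS])
    settings = rng_settings.choice(len(SETTINGS), size=n, p=dist / dist.sum())

    sub_index = {sub.id: i + 1 for i, sub in enumerate(model.sub_conditions)}
    deaths: dict[tuple[str, str], float] = {}
    cases: dict[str, float] = {}
    pending_links: dict[str, list[_Stream]] = {
        sub.id: [] for sub in model.neonatal_subconditions
    }

    for sub in model.maternal_subconditions:
        rng = np.random.default_rng([config.seed, sub_index[sub.id]])
        incident = rng.random(n) < sub.unprevented_incidence
        tally = _simulate_subcondition(
            rng, model, params, sub,
            [_Stream(incident=incident, settings=settings, source="background")],
        )
        deaths[(sub.id, "maternal")] = float(tally.deaths)
        deaths[(sub.id, "fetal")] = float(tally.fetal_deaths)
        cases[sub.id] = float(tally.cases)
        for neo_id, extra in tally.link_streams.items():
            pending_links[neo_id].extend(extra)

    for sub in model.neonatal_subconditions:
        rng = np.random.default_rng([config.seed, sub_index[sub.id]])
        incident = rng.random(n) < sub.unprevented_incidence
        streams = [_Stream(incident=incident, settings=settings, source="background")]
        streams.extend(pending_links[sub.id])
        tally = _simulate_subcondition(rng, model, params, sub, streams)
        deaths[(sub.id, "neonatal")] = float(tally.deaths)
        cases[sub.id] = float(tally.cases)

    totals = {
        pop: sum(v for (_, p), v in deaths.items() if p == pop)
        for pop in ("maternal", "fetal", "neonatal")
    }
    return ScenarioResult(
        scenario_id=f"{params.scenario_id}::sim",
        births=float(n),
        deaths=deaths,
        cases=cases,
        totals=totals,
        model_hash=model.content_hash(),
        params_hash=params.content_hash(),
    )


@dataclass(frozen=True)
class ComparisonRow:
    subcondition_id: str
    population: str
    analytic_rate: float
    simulated_rate: float
    z: float
    flagged: bool


def compare(
    analytic: ScenarioResult,
    simulated: ScenarioResult,
    n: int,
    threshold: float = 4.0,
) -> list[ComparisonRow]:
    """Per-sub-condition z-scores of simulated vs analytic death rates.

    z = (sim_rate - analytic_rate) / sqrt(p (1 - p) / n); rows with
    ``|z| > threshold`` are flagged.  Degenerate rates (SE = 0) flag on any
    mismatch.
    """
    if analytic.model_hash != simulated.model_hash:
        raise ConfigurationError("results come from different model definitions")
    rows: list[ComparisonRow] = []
    for key in sorted(set(analytic.deaths) | set(simulated.deaths)):
        sub_id, pop = key
        p = analytic.deaths.get(key, 0.0) / analytic.births if analytic.births else 0.0
        p_hat = simulated.deaths.get(key, 0.0) / simulated.births
        se = float(np.sqrt(max(p * (1.0 - p), 0.0) / n))
        if se == 0.0:
            z = 0.0 if p_hat == p else float("inf")
        else:
            z = (p_hat - p) / se
        rows.append(
            ComparisonRow(
                subcondition_id=sub_id,
                population=pop,
                analytic_rate=p,
                simulated_rate=p_hat,
                z=z,
                flagged=abs(z) > threshold,
            )
        )
    return rows


def comparison_to_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([row.__dict__ for row in rows])
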