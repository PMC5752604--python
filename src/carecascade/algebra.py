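"""Pure-probability composition of interventions.

Coverage, layered combination, line cascades, exhaustive stage-outcome
enumeration, and usage constraints.  Everything here is side-effect free and
operates on plain probabilities; the cohort engine is the only consumer.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .schema import InterventionSpec, ModelDefinition, Setting

__all__ = [
    "Stage",
    "AppliedIntervention",
    "coverage",
    "success",
    "compose_layers",
    "compose_lines",
    "combine_stage",
    "enumerate_stage",
    "StageOutcome",
    "check_usage_constraints",
    "UsageViolation",
]


class Stage(str, enum.Enum):
    PREVENTION = "prevention"
    DIAGNOSIS = "diagnosis"
    TREATMENT = "treatment"


def _check_prob(value: float, name: str) -> float:
    if math.isnan(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class AppliedIntervention:
    """One intervention as experienced by an eligible person in one setting.

    ``receive_probability`` is penetration x utilization; ``success_probability``
    additionally multiplies in efficacy, so success <= receive always holds.
    """

    intervention_id: str
    setting: Setting
    receive_probability: float
    success_probability: float
    stage: Stage

    def __post_init__(self) -> None:
        _check_prob(self.receive_probability, "receive_probability")
        _check_prob(self.success_probability, "success_probability")
        if self.success_probability > self.receive_probability + 1e-15:
            raise ValueError(
                f"success_probability {self.success_probability} exceeds "
                f"receive_probability {self.receive_probability}"
            )

    @property
    def conditional_efficacy(self) -> float:
        """P(success | received). Zero when the intervention is never received."""
        if self.receive_probability == 0.0:
            return 0.0
        return min(1.0, self.success_probability / self.receive_probability)


def coverage(penetration: float, utilization: float) -> float:
    """Probability an eligible person actually receives the intervention."""
    return _check_prob(penetration, "penetration") * _check_prob(utilization, "utilization")


def success(coverage_: float, efficacy: float) -> float:
    """Probability of receipt AND success under ideal-condition efficacy."""
    return _check_prob(coverage_, "coverage") * _check_prob(efficacy, "efficacy")


def compose_layers(successes: Iterable[float]) -> float:
    """Combined success of independent, order-free interventions.

    Returns ``1 - prod(1 - s_i)``; the empty combination is 0.
    """
    failure = 1.0
    for s in successes:
        failure *= 1.0 - _check_prob(s, "layer success")
    return 1.0 - failure


def compose_lines(
    lines: Sequence[tuple[float, float]],
) -> tuple[float, list[float]]:
    """Collapse an ordered cascade of (receive_prob, efficacy) lines.

    Line 1 is administered with its receive probability; line k > 1 only to
    those who received line k-1 AND failed it.  Returns the overall success
    probability and the administered mass fraction of each line.
    """
    administered: list[float] = []
    overall = 0.0
    eligible = 1.0  # mass fraction still eligible for the next line
    for recv, eff in lines:
        _check_prob(recv, "receive probability")
        _check_prob(eff, "efficacy")
        given = eligible * recv
        administered.append(given)
        overall += given * eff
        eligible = given * (1.0 - eff)
    return overall, administered


def combine_stage(
    layers: Sequence[AppliedIntervention],
    line_groups: Sequence[Sequence[AppliedIntervention]] = (),
) -> float:
    """Overall success probability of one stage of care for one sub-condition.

    Each line group collapses to a single success probability which then
    combines with the layer successes as if independent.
    """
    seen: set[str] = set()
    for ai in itertools.chain(layers, *line_groups):
        if ai.intervention_id in seen:
            raise ConfigurationError(
                f"intervention {ai.intervention_id!r} appears in more than one "
                "layer/line group of the same stage"
            )
        seen.add(ai.intervention_id)
    parts = [ai.success_probability for ai in layers]
    for group in line_groups:
        overall, _ = compose_lines(
            [(ai.receive_probability, ai.conditional_efficacy) for ai in group]
        )
        parts.append(overall)
    return compose_layers(parts)


@dataclass(frozen=True)
class StageOutcome:
    """One joint outcome of a stage: which interventions were given/succeeded."""

    probability: float
    administered: frozenset[str]
    succeeded: frozenset[str]


def enumerate_stage(
    layers: Sequence[AppliedIntervention],
    line_groups: Sequence[Sequence[AppliedIntervention]] = (),
) -> list[StageOutcome]:
    """Exhaustive joint outcome distribution of one stage.

    Layers contribute three outcomes each (not received / received-and-failed /
    received-and-succeeded); a line group contributes one outcome per point at
    which the cascade can stop.  Units are independent, so the joint space is
    the product.  Used by the engine for administered-intervention tallies and
    for exact fetal/neonatal benefit expectations; its implied success
    probability equals :func:`combine_stage` (tested property).
    """
    unit_outcomes: list[list[StageOutcome]] = []
    for ai in layers:
        c, s = ai.receive_probability, ai.success_probability
        unit_outcomes.append(
            [
                StageOutcome(1.0 - c, frozenset(), frozenset()),
                StageOutcome(c - s, frozenset({ai.intervention_id}), frozenset()),
                StageOutcome(s, frozenset({ai.intervention_id}),
                             frozenset({ai.intervention_id})),
            ]
        )
    for group in line_groups:
        outcomes: list[StageOutcome] = []
        reached = 1.0
        given: tuple[str, ...] = ()
        for ai in group:
            c, e = ai.receive_probability, ai.conditional_efficacy
            # cascade stops: this line never received
            outcomes.append(
                StageOutcome(reached * (1.0 - c), frozenset(given), frozenset())
            )
            given = given + (ai.intervention_id,)
            # this line received and succeeded
            outcomes.append(
                StageOutcome(reached * c * e, frozenset(given),
                             frozenset({ai.intervention_id}))
            )
            reached *= c * (1.0 - e)
        # all lines received, all failed
        outcomes.append(StageOutcome(reached, frozenset(given), frozenset()))
        unit_outcomes.append(outcomes)

    if not unit_outcomes:
        return [StageOutcome(1.0, frozenset(), frozenset())]
    joint: list[StageOutcome] = []
    for combo in itertools.product(*unit_outcomes):
        p = 1.0
        administered: frozenset[str] = frozenset()
        succeeded: frozenset[str] = frozenset()
        for out in combo:
            p *= out.probability
            administered |= out.administered
            succeeded |= out.succeeded
        if p > 0.0:
            joint.append(StageOutcome(p, administered, succeeded))
    return joint


@dataclass(frozen=True)
class UsageViolation:
    intervention_id: str
    count: int
    reason: str


def check_usage_constraints(
    pathway: Sequence[AppliedIntervention],
    model: ModelDefinition,
) -> list[UsageViolation]:
    """Flag single-use interventions appearing more than once in one pathway.

    Repeated ids are permitted when every occurrence carries distinct
    timing_tags (e.g. the same uterotonic at the prevention stage and again at
    the treatment stage).
    """
    by_id: dict[str, list[InterventionSpec]] = {}
    for ai in pathway:
        spec = model.intervention_by_key(ai.intervention_id)
        by_id.setdefault(spec.id, []).append(spec)
    violations: list[UsageViolation] = []
    for iv_id, specs in by_id.items():
        if len(specs) < 2 or not any(s.single_use for s in specs):
            continue
        tags = [s.timing_tags for s in specs]
        if len(set(tags)) == len(tags) and all(tags):
            continue  # distinct timing stages: allowed
        violations.append(
            UsageViolation(
                intervention_id=iv_id,
                count=len(specs),
                reason="single-use intervention administered more than once in a "
                "pathway without distinct timing tags",
            )
        )
    return violations
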