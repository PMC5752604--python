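"""Domain types, validation, and reading/writing of model and scenario files.

The on-disk dialect is YAML with a ``schema_version`` gate.  All probabilities
are stored as decimals in ``[0, 1]``, never percentages.  Loading always
validates; a loaded object is safe to hand to the engine.
"""

from __future__ import annotations

import copy
import enum
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .errors import SchemaVersionError, ValidationError

SCHEMA_VERSION = "1.0"

__all__ = [
    "SCHEMA_VERSION",
    "Setting",
    "SETTINGS",
    "PopulationType",
    "InterventionKind",
    "CoverageSpec",
    "Composition",
    "NeonatalLink",
    "SubConditionSpec",
    "InterventionSpec",
    "TransferRule",
    "ParameterVariant",
    "Bounds",
    "ScenarioParameters",
    "ModelDefinition",
    "effective_transfers_for",
    "load_model",
    "save_model",
    "load_scenario",
    "save_scenario",
]


class Setting(str, enum.Enum):
    """A care setting. Exactly three exist, ordered home < clinic < hospital."""

    HOME = "home"
    CLINIC = "clinic"
    HOSPITAL = "hospital"

    @property
    def rank(self) -> int:
        return _SETTING_RANK[self]


_SETTING_RANK = {Setting.HOME: 0, Setting.CLINIC: 1, Setting.HOSPITAL: 2}
SETTINGS: tuple[Setting, ...] = (Setting.HOME, Setting.CLINIC, Setting.HOSPITAL)


class PopulationType(str, enum.Enum):
    MATERNAL = "maternal"
    FETAL = "fetal"
    NEONATAL = "neonatal"


class InterventionKind(str, enum.Enum):
    PREVENTIVE = "preventive"
    DIAGNOSTIC = "diagnostic"
    TREATMENT = "treatment"


def _prob(value: Any, path: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValidationError(path, f"expected a number, got {value!r}")
    v = float(value)
    if math.isnan(v) or not 0.0 <= v <= 1.0:
        raise ValidationError(path, f"probability {v!r} outside [0, 1]")
    return v


def _string(value: Any, path: str) -> str:
    if not isinstance(value, str) or not value:
        raise ValidationError(path, f"expected a non-empty string, got {value!r}")
    return value


def _setting(value: Any, path: str) -> Setting:
    try:
        return Setting(value)
    except ValueError:
        raise ValidationError(
            path, f"unknown setting {value!r}; must be one of "
            f"{[s.value for s in SETTINGS]}"
        ) from None


def _expect_mapping(value: Any, path: str) -> Mapping[str, Any]:
    if not isinstance(value, Mapping):
        raise ValidationError(path, f"expected a mapping, got {type(value).__name__}")
    return value


def _reject_unknown(d: Mapping[str, Any], allowed: Iterable[str], path: str) -> None:
    extra = set(d) - set(allowed)
    if extra:
        raise ValidationError(path, f"unknown field(s): {sorted(extra)}")


@dataclass(frozen=True)
class CoverageSpec:
    """Per-setting availability (penetration) and appropriate use (utilization)."""

    penetration: float
    utilization: float

    def __post_init__(self) -> None:
        _prob(self.penetration, "penetration")
        _prob(self.utilization, "utilization")

    def to_dict(self) -> dict[str, float]:
        return {"penetration": self.penetration, "utilization": self.utilization}

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "CoverageSpec":
        d = _expect_mapping(d, path)
        _reject_unknown(d, ("penetration", "utilization"), path)
        return cls(
            penetration=_prob(d.get("penetration", 0.0), f"{path}.penetration"),
            utilization=_prob(d.get("utilization", 0.0), f"{path}.utilization"),
        )


ZERO_COVERAGE = CoverageSpec(0.0, 0.0)


@dataclass(frozen=True)
class Composition:
    """How an intervention combines with others targeting the same sub-condition.

    ``layer`` interventions are order-free and independent; ``line`` interventions
    form an ordered cascade where line k is only reached after line k-1 was
    received and failed.
    """

    mode: str  # "layer" | "line"
    order: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("layer", "line"):
            raise ValidationError("composition.mode", f"unknown mode {self.mode!r}")
        if self.mode == "line":
            if not isinstance(self.order, int) or self.order < 1:
                raise ValidationError(
                    "composition.order", "line interventions need a positive integer order"
                )
        elif self.order is not None:
            raise ValidationError("composition.order", "layer interventions take no order")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"mode": self.mode}
        if self.order is not None:
            d["order"] = self.order
        return d

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "Composition":
        d = _expect_mapping(d, path)
        _reject_unknown(d, ("mode", "order"), path)
        try:
            return cls(mode=d.get("mode", "layer"), order=d.get("order"))
        except ValidationError as exc:
            raise ValidationError(f"{path}.{exc.path}", exc.message) from None


LAYER = Composition("layer")


@dataclass(frozen=True)
class NeonatalLink:
    """Incremental neonatal-condition incidence given a maternal sub-condition.

    ``untreated`` applies to case mass whose maternal condition was not treated
    successfully; ``treated`` to successfully treated mass (before any further
    per-treatment neonatal_efficacy reduction).
    """

    untreated: float
    treated: float

    def to_dict(self) -> dict[str, float]:
        return {"untreated": self.untreated, "treated": self.treated}

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "NeonatalLink":
        if isinstance(d, (int, float)) and not isinstance(d, bool):
            rate = _prob(d, path)
            return cls(untreated=rate, treated=rate)
        d = _expect_mapping(d, path)
        _reject_unknown(d, ("untreated", "treated"), path)
        untreated = _prob(d.get("untreated", 0.0), f"{path}.untreated")
        treated = _prob(d.get("treated", untreated), f"{path}.treated")
        return cls(untreated=untreated, treated=treated)


@dataclass(frozen=True)
class SubConditionSpec:
    """A cause-specific etiology with incidence, case fatality, and outcome links."""

    id: str
    condition_id: str
    population: PopulationType
    unprevented_incidence: float
    untreated_cfr: float
    treated_cfr: float = 0.0
    fetal_death_rate_untreated: float | None = None
    fetal_death_rate_treated: float | None = None
    neonatal_links: dict[str, NeonatalLink] = field(default_factory=dict)

    @property
    def is_maternal(self) -> bool:
        return self.population is PopulationType.MATERNAL

    def validate(self, path: str) -> None:
        _prob(self.unprevented_incidence, f"{path}.unprevented_incidence")
        _prob(self.untreated_cfr, f"{path}.untreated_cfr")
        _prob(self.treated_cfr, f"{path}.treated_cfr")
        if self.treated_cfr > self.untreated_cfr:
            raise ValidationError(
                f"{path}.treated_cfr",
                f"treated_cfr {self.treated_cfr} exceeds untreated_cfr {self.untreated_cfr}",
            )
        if self.population is PopulationType.FETAL:
            raise ValidationError(
                f"{path}.population",
                "fetal outcomes arise only as consequences of maternal sub-conditions; "
                "sub-conditions must be maternal or neonatal",
            )
        if self.population is PopulationType.NEONATAL:
            if (
                self.fetal_death_rate_untreated is not None
                or self.fetal_death_rate_treated is not None
                or self.neonatal_links
            ):
                raise ValidationError(
                    path, "neonatal sub-conditions carry no fetal rates or neonatal links"
                )
        if (self.fetal_death_rate_treated is None) != (self.fetal_death_rate_untreated is None):
            raise ValidationError(
                path, "fetal death rates must be given as an (untreated, treated) pair"
            )
        if self.fetal_death_rate_untreated is not None:
            fu = _prob(self.fetal_death_rate_untreated, f"{path}.fetal_death_rate_untreated")
            ft = _prob(self.fetal_death_rate_treated, f"{path}.fetal_death_rate_treated")
            if ft > fu:
                raise ValidationError(
                    f"{path}.fetal_death_rate_treated",
                    f"treated fetal rate {ft} exceeds untreated rate {fu}",
                )
        for neo_id, link in self.neonatal_links.items():
            lp = f"{path}.neonatal_links[{neo_id}]"
            _prob(link.untreated, f"{lp}.untreated")
            _prob(link.treated, f"{lp}.treated")
            if link.treated > link.untreated:
                raise ValidationError(
                    f"{lp}.treated", "treated link rate exceeds untreated link rate"
                )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "id": self.id,
            "condition_id": self.condition_id,
            "population": self.population.value,
            "unprevented_incidence": self.unprevented_incidence,
            "untreated_cfr": self.untreated_cfr,
            "treated_cfr": self.treated_cfr,
        }
        if self.fetal_death_rate_untreated is not None:
            d["fetal_death_rate_untreated"] = self.fetal_death_rate_untreated
            d["fetal_death_rate_treated"] = self.fetal_death_rate_treated
        if self.neonatal_links:
            d["neonatal_links"] = {
                k: v.to_dict() for k, v in sorted(self.neonatal_links.items())
            }
        return d

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "SubConditionSpec":
        d = _expect_mapping(d, path)
        _reject_unknown(
            d,
            (
                "id",
                "condition_id",
                "population",
                "unprevented_incidence",
                "untreated_cfr",
                "treated_cfr",
                "fetal_death_rate_untreated",
                "fetal_death_rate_treated",
                "neonatal_links",
            ),
            path,
        )
        try:
            population = PopulationType(d.get("population", "maternal"))
        except ValueError:
            raise ValidationError(
                f"{path}.population", f"unknown population {d.get('population')!r}"
            ) from None
        fu = d.get("fetal_death_rate_untreated")
        ft = d.get("fetal_death_rate_treated", fu)
        links_raw = d.get("neonatal_links", {}) or {}
        links = {
            _string(k, f"{path}.neonatal_links"): NeonatalLink.from_dict(
                v, f"{path}.neonatal_links[{k}]"
            )
            for k, v in _expect_mapping(links_raw, f"{path}.neonatal_links").items()
        }
        spec = cls(
            id=_string(d.get("id"), f"{path}.id"),
            condition_id=_string(d.get("condition_id"), f"{path}.condition_id"),
            population=population,
            unprevented_incidence=_prob(
                d.get("unprevented_incidence"), f"{path}.unprevented_incidence"
            ),
            untreated_cfr=_prob(d.get("untreated_cfr"), f"{path}.untreated_cfr"),
            treated_cfr=_prob(d.get("treated_cfr", 0.0), f"{path}.treated_cfr"),
            fetal_death_rate_untreated=None if fu is None else float(fu),
            fetal_death_rate_treated=None if ft is None else float(ft),
            neonatal_links=links,
        )
        spec.validate(path)
        return spec


@dataclass(frozen=True)
class InterventionSpec:
    """A preventive, diagnostic, or treatment action with per-setting coverage.

    ``efficacy`` is a single setting-independent value; ``coverage`` holds the
    per-setting penetration/utilization defaults that scenarios may override.
    ``fetal_efficacy``/``neonatal_efficacy`` are a treatment's distinct benefit
    on the fetal death rate and on linked neonatal-condition incidence among
    successfully treated cases.
    """

    id: str
    kind: InterventionKind
    target_subcondition_ids: frozenset[str]
    efficacy: float
    coverage: dict[Setting, CoverageSpec] = field(default_factory=dict)
    fetal_efficacy: float | None = None
    neonatal_efficacy: float | None = None
    composition: Composition = LAYER
    single_use: bool = False
    timing_tags: frozenset[str] = frozenset()

    @property
    def key(self) -> str:
        """Unique key; disambiguates dual-timing entries sharing an id."""
        if not self.timing_tags:
            return self.id
        return f"{self.id}@{'+'.join(sorted(self.timing_tags))}"

    def coverage_at(self, setting: Setting) -> CoverageSpec:
        return self.coverage.get(setting, ZERO_COVERAGE)

    def validate(self, path: str) -> None:
        _prob(self.efficacy, f"{path}.efficacy")
        if self.fetal_efficacy is not None:
            _prob(self.fetal_efficacy, f"{path}.fetal_efficacy")
        if self.neonatal_efficacy is not None:
            _prob(self.neonatal_efficacy, f"{path}.neonatal_efficacy")
        if not self.target_subcondition_ids:
            raise ValidationError(f"{path}.targets", "intervention targets no sub-condition")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "id": self.id,
            "kind": self.kind.value,
            "targets": sorted(self.target_subcondition_ids),
            "efficacy": self.efficacy,
            "coverage": {
                s.value: self.coverage_at(s).to_dict() for s in SETTINGS
            },
            "composition": self.composition.to_dict(),
        }
        if self.fetal_efficacy is not None:
            d["fetal_efficacy"] = self.fetal_efficacy
        if self.neonatal_efficacy is not None:
            d["neonatal_efficacy"] = self.neonatal_efficacy
        if self.single_use:
            d["single_use"] = True
        if self.timing_tags:
            d["timing_tags"] = sorted(self.timing_tags)
        return d

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "InterventionSpec":
        d = _expect_mapping(d, path)
        _reject_unknown(
            d,
            (
                "id",
                "kind",
                "targets",
                "efficacy",
                "coverage",
                "composition",
                "fetal_efficacy",
                "neonatal_efficacy",
                "single_use",
                "timing_tags",
            ),
            path,
        )
        try:
            kind = InterventionKind(d.get("kind"))
        except ValueError:
            raise ValidationError(f"{path}.kind", f"unknown kind {d.get('kind')!r}") from None
        targets = d.get("targets") or []
        if not isinstance(targets, (list, tuple)):
            raise ValidationError(f"{path}.targets", "expected a list of sub-condition ids")
        coverage_raw = _expect_mapping(d.get("coverage", {}) or {}, f"{path}.coverage")
        coverage = {s: ZERO_COVERAGE for s in SETTINGS}
        for key, val in coverage_raw.items():
            s = _setting(key, f"{path}.coverage")
            coverage[s] = CoverageSpec.from_dict(val, f"{path}.coverage.{s.value}")
        fe = d.get("fetal_efficacy")
        ne = d.get("neonatal_efficacy")
        spec = cls(
            id=_string(d.get("id"), f"{path}.id"),
            kind=kind,
            target_subcondition_ids=frozenset(
                _string(t, f"{path}.targets") for t in targets
            ),
            efficacy=_prob(d.get("efficacy"), f"{path}.efficacy"),
            coverage=coverage,
            fetal_efficacy=None if fe is None else float(fe),
            neonatal_efficacy=None if ne is None else float(ne),
            composition=Composition.from_dict(
                d.get("composition", {"mode": "layer"}), f"{path}.composition"
            ),
            single_use=bool(d.get("single_use", False)),
            timing_tags=frozenset(d.get("timing_tags") or ()),
        )
        spec.validate(path)
        return spec


@dataclass(frozen=True)
class TransferRule:
    """Upward movement of diagnosed patients between care settings."""

    from_setting: Setting
    to_setting: Setting
    probability: float
    applicable_subcondition_ids: frozenset[str]

    def validate(self, path: str) -> None:
        _prob(self.probability, f"{path}.probability")
        if self.to_setting.rank <= self.from_setting.rank:
            raise ValidationError(
                f"{path}.to",
                f"transfers must move up the care ladder "
                f"({self.from_setting.value} -> {self.to_setting.value} does not)",
            )
        if not self.applicable_subcondition_ids:
            raise ValidationError(f"{path}.applies_to", "transfer rule applies to nothing")

    def to_dict(self) -> dict[str, Any]:
        return {
            "from": self.from_setting.value,
            "to": self.to_setting.value,
            "probability": self.probability,
            "applies_to": sorted(self.applicable_subcondition_ids),
        }

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "TransferRule":
        d = _expect_mapping(d, path)
        _reject_unknown(d, ("from", "to", "probability", "applies_to"), path)
        rule = cls(
            from_setting=_setting(d.get("from"), f"{path}.from"),
            to_setting=_setting(d.get("to"), f"{path}.to"),
            probability=_prob(d.get("probability"), f"{path}.probability"),
            applicable_subcondition_ids=frozenset(
                _string(t, f"{path}.applies_to") for t in (d.get("applies_to") or ())
            ),
        )
        rule.validate(path)
        return rule


@dataclass
class ModelDefinition:
    """The condition graph: sub-conditions, interventions, and transfer rules."""

    sub_conditions: list[SubConditionSpec]
    interventions: list[InterventionSpec]
    transfers: list[TransferRule]
    schema_version: str = SCHEMA_VERSION

    # -- lookups -------------------------------------------------------------

    def subcondition(self, sub_id: str) -> SubConditionSpec:
        for sub in self.sub_conditions:
            if sub.id == sub_id:
                return sub
        raise KeyError(sub_id)

    @property
    def maternal_subconditions(self) -> list[SubConditionSpec]:
        return [s for s in self.sub_conditions if s.population is PopulationType.MATERNAL]

    @property
    def neonatal_subconditions(self) -> list[SubConditionSpec]:
        return [s for s in self.sub_conditions if s.population is PopulationType.NEONATAL]

    def interventions_for(
        self, sub_id: str, kind: InterventionKind
    ) -> list[InterventionSpec]:
        return [
            iv
            for iv in self.interventions
            if iv.kind is kind and sub_id in iv.target_subcondition_ids
        ]

    def intervention_by_key(self, key: str) -> InterventionSpec:
        for iv in self.interventions:
            if iv.key == key:
                return iv
        raise KeyError(key)

    def transfers_for(self, sub_id: str, from_setting: Setting) -> list[TransferRule]:
        return [
            t
            for t in self.transfers
            if t.from_setting is from_setting and sub_id in t.applicable_subcondition_ids
        ]

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise SchemaVersionError(
                "schema_version",
                f"unsupported version {self.schema_version!r}; expected {SCHEMA_VERSION!r}",
            )
        sub_ids: set[str] = set()
        for i, sub in enumerate(self.sub_conditions):
            path = f"sub_conditions[{i}]"
            sub.validate(path)
            if sub.id in sub_ids:
                raise ValidationError(f"{path}.id", f"duplicate sub-condition id {sub.id!r}")
            sub_ids.add(sub.id)
        neonatal_ids = {s.id for s in self.neonatal_subconditions}
        for i, sub in enumerate(self.sub_conditions):
            for neo_id in sub.neonatal_links:
                if neo_id not in neonatal_ids:
                    raise ValidationError(
                        f"sub_conditions[{i}].neonatal_links[{neo_id}]",
                        "link target is not a neonatal sub-condition",
                    )
        seen_keys: dict[str, InterventionSpec] = {}
        ids_to_tags: dict[str, list[frozenset[str]]] = {}
        for i, iv in enumerate(self.interventions):
            path = f"interventions[{i}]"
            iv.validate(path)
            if iv.key in seen_keys:
                raise ValidationError(
                    f"{path}.id",
                    f"duplicate intervention {iv.id!r}; reuse of an id requires "
                    "distinct timing_tags",
                )
            seen_keys[iv.key] = iv
            ids_to_tags.setdefault(iv.id, []).append(iv.timing_tags)
            for target in iv.target_subcondition_ids:
                if target not in sub_ids:
                    raise ValidationError(
                        f"{path}.targets", f"unknown sub-condition id {target!r}"
                    )
        # line orders unique and contiguous from 1 within each (sub-condition, kind)
        for sub_id in sub_ids:
            for kind in InterventionKind:
                orders = sorted(
                    iv.composition.order
                    for iv in self.interventions_for(sub_id, kind)
                    if iv.composition.mode == "line"
                )
                if orders and orders != list(range(1, len(orders) + 1)):
                    raise ValidationError(
                        f"interventions",
                        f"line orders for ({sub_id!r}, {kind.value}) must be unique "
                        f"and contiguous from 1, got {orders}",
                    )
        for i, rule in enumerate(self.transfers):
            path = f"transfers[{i}]"
            rule.validate(path)
            for target in rule.applicable_subcondition_ids:
                if target not in sub_ids:
                    raise ValidationError(
                        f"{path}.applies_to", f"unknown sub-condition id {target!r}"
                    )
        # outgoing transfer mass per (setting, sub-condition) bounded by 1
        for sub_id in sub_ids:
            for setting in SETTINGS:
                total = sum(r.probability for r in self.transfers_for(sub_id, setting))
                if total > 1.0 + 1e-12:
                    raise ValidationError(
                        "transfers",
                        f"outgoing transfer probabilities from {setting.value} for "
                        f"{sub_id!r} sum to {total} > 1",
                    )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "sub_conditions": [s.to_dict() for s in self.sub_conditions],
            "interventions": [iv.to_dict() for iv in self.interventions],
            "transfers": [t.to_dict() for t in self.transfers],
        }

    @classmethod
    def from_dict(cls, d: Any) -> "ModelDefinition":
        d = _expect_mapping(d, "<root>")
        _reject_unknown(
            d, ("schema_version", "sub_conditions", "interventions", "transfers"), "<root>"
        )
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                "schema_version",
                f"unsupported version {version!r}; expected {SCHEMA_VERSION!r}",
            )
        model = cls(
            schema_version=version,
            sub_conditions=[
                SubConditionSpec.from_dict(s, f"sub_conditions[{i}]")
                for i, s in enumerate(d.get("sub_conditions") or [])
            ],
            interventions=[
                InterventionSpec.from_dict(iv, f"interventions[{i}]")
                for i, iv in enumerate(d.get("interventions") or [])
            ],
            transfers=[
                TransferRule.from_dict(t, f"transfers[{i}]")
                for i, t in enumerate(d.get("transfers") or [])
            ],
        )
        model.validate()
        return model


@dataclass
class ParameterVariant:
    """A low or high bound variant: rate and coverage overrides."""

    rate_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    coverage_overrides: dict[str, dict[Setting, CoverageSpec]] = field(default_factory=dict)

    _RATE_FIELDS = (
        "unprevented_incidence",
        "untreated_cfr",
        "treated_cfr",
        "fetal_death_rate_untreated",
        "fetal_death_rate_treated",
    )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        if self.rate_overrides:
            d["rate_overrides"] = {
                k: dict(sorted(v.items())) for k, v in sorted(self.rate_overrides.items())
            }
        if self.coverage_overrides:
            d["coverage_overrides"] = {
                iv: {s.value: c.to_dict() for s, c in sorted(m.items(), key=lambda kv: kv[0].rank)}
                for iv, m in sorted(self.coverage_overrides.items())
            }
        return d

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "ParameterVariant":
        d = _expect_mapping(d, path)
        _reject_unknown(d, ("rate_overrides", "coverage_overrides"), path)
        rates: dict[str, dict[str, float]] = {}
        for sub_id, fields_ in _expect_mapping(
            d.get("rate_overrides", {}) or {}, f"{path}.rate_overrides"
        ).items():
            fp = f"{path}.rate_overrides[{sub_id}]"
            fields_ = _expect_mapping(fields_, fp)
            _reject_unknown(fields_, cls._RATE_FIELDS, fp)
            rates[sub_id] = {k: _prob(v, f"{fp}.{k}") for k, v in fields_.items()}
        covs: dict[str, dict[Setting, CoverageSpec]] = {}
        for iv_id, by_setting in _expect_mapping(
            d.get("coverage_overrides", {}) or {}, f"{path}.coverage_overrides"
        ).items():
            cp = f"{path}.coverage_overrides[{iv_id}]"
            covs[iv_id] = {
                _setting(s, cp): CoverageSpec.from_dict(c, f"{cp}.{s}")
                for s, c in _expect_mapping(by_setting, cp).items()
            }
        return cls(rate_overrides=rates, coverage_overrides=covs)


@dataclass
class Bounds:
    low: ParameterVariant
    high: ParameterVariant

    def to_dict(self) -> dict[str, Any]:
        return {"low": self.low.to_dict(), "high": self.high.to_dict()}

    @classmethod
    def from_dict(cls, d: Any, path: str) -> "Bounds":
        d = _expect_mapping(d, path)
        _reject_unknown(d, ("low", "high"), path)
        return cls(
            low=ParameterVariant.from_dict(d.get("low", {}) or {}, f"{path}.low"),
            high=ParameterVariant.from_dict(d.get("high", {}) or {}, f"{path}.high"),
        )


@dataclass
class ScenarioParameters:
    """The full numeric parameterization of one run.

    ``coverage`` is the *resolved* effective per-setting penetration/utilization
    for every intervention key (model defaults with scenario overrides applied).
    ``coverage_overrides`` preserves what the scenario file stated, for
    round-tripping.
    """

    scenario_id: str
    births: float
    setting_distribution: dict[Setting, float]
    coverage: dict[str, dict[Setting, CoverageSpec]]
    coverage_overrides: dict[str, dict[Setting, CoverageSpec]] = field(default_factory=dict)
    transfer_overrides: dict[Setting, dict[Setting, float]] = field(default_factory=dict)
    bounds: Bounds | None = None
    mortality_adjustment: float = 1.0

    def coverage_at(self, key: str, setting: Setting) -> CoverageSpec:
        return self.coverage.get(key, {}).get(setting, ZERO_COVERAGE)

    def content_hash(self) -> str:
        payload = {
            "scenario_id": self.scenario_id,
            "births": self.births,
            "setting_distribution": {s.value: f for s, f in self.setting_distribution.items()},
            "coverage": {
                k: {s.value: c.to_dict() for s, c in m.items()}
                for k, m in self.coverage.items()
            },
            "transfer_overrides": {
                f.value: {t.value: p for t, p in m.items()}
                for f, m in self.transfer_overrides.items()
            },
            "mortality_adjustment": self.mortality_adjustment,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self, model: ModelDefinition) -> None:
        if not isinstance(self.births, (int, float)) or self.births < 0:
            raise ValidationError("births", f"births must be >= 0, got {self.births!r}")
        total = sum(self.setting_distribution.get(s, 0.0) for s in SETTINGS)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                "setting_distribution", f"fractions sum to {total!r}, expected 1"
            )
        for s, frac in self.setting_distribution.items():
            _prob(frac, f"setting_distribution.{s.value}")
        if self.mortality_adjustment < 0:
            raise ValidationError("mortality_adjustment", "must be >= 0")
        known_ids = {iv.id for iv in model.interventions}
        known_keys = {iv.key for iv in model.interventions}
        for key in self.coverage_overrides:
            if key not in known_ids and key not in known_keys:
                raise ValidationError(
                    f"coverage_overrides[{key}]", "unknown intervention id"
                )
        for from_s, by_to in self.transfer_overrides.items():
            for to_s, p in by_to.items():
                tp = f"transfer_overrides.{from_s.value}.{to_s.value}"
                _prob(p, tp)
                if to_s.rank <= from_s.rank:
                    raise ValidationError(tp, "transfers must move up the care ladder")
        for sub in model.sub_conditions:
            for from_s in SETTINGS:
                total = sum(
                    r.probability
                    for r in effective_transfers_for(model, self, sub.id, from_s)
                )
                if total > 1.0 + 1e-12:
                    raise ValidationError(
                        f"transfer_overrides.{from_s.value}",
                        f"effective outgoing transfer probabilities for {sub.id!r} "
                        f"sum to {total} > 1",
                    )
        if self.bounds is not None:
            sub_ids = {s.id for s in model.sub_conditions}
            for name, variant in (("low", self.bounds.low), ("high", self.bounds.high)):
                for sub_id in variant.rate_overrides:
                    if sub_id not in sub_ids:
                        raise ValidationError(
                            f"bounds.{name}.rate_overrides[{sub_id}]",
                            "unknown sub-condition id",
                        )
                for key in variant.coverage_overrides:
                    if key not in known_ids and key not in known_keys:
                        raise ValidationError(
                            f"bounds.{name}.coverage_overrides[{key}]",
                            "unknown intervention id",
                        )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "schema_version": SCHEMA_VERSION,
            "scenario_id": self.scenario_id,
            "births": self.births,
            "setting_distribution": {
                s.value: self.setting_distribution.get(s, 0.0) for s in SETTINGS
            },
        }
        if self.mortality_adjustment != 1.0:
            d["mortality_adjustment"] = self.mortality_adjustment
        if self.coverage_overrides:
            d["coverage_overrides"] = {
                iv: {
                    s.value: c.to_dict()
                    for s, c in sorted(m.items(), key=lambda kv: kv[0].rank)
                }
                for iv, m in sorted(self.coverage_overrides.items())
            }
        if self.transfer_overrides:
            d["transfer_overrides"] = {
                f.value: {
                    t.value: p for t, p in sorted(m.items(), key=lambda kv: kv[0].rank)
                }
                for f, m in sorted(
                    self.transfer_overrides.items(), key=lambda kv: kv[0].rank
                )
            }
        if self.bounds is not None:
            d["bounds"] = self.bounds.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Any, model: ModelDefinition) -> "ScenarioParameters":
        d = _expect_mapping(d, "<root>")
        _reject_unknown(
            d,
            (
                "schema_version",
                "scenario_id",
                "births",
                "setting_distribution",
                "coverage_overrides",
                "transfer_overrides",
                "bounds",
                "mortality_adjustment",
            ),
            "<root>",
        )
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                "schema_version",
                f"unsupported version {version!r}; expected {SCHEMA_VERSION!r}",
            )
        dist_raw = _expect_mapping(
            d.get("setting_distribution", {}) or {}, "setting_distribution"
        )
        dist = {
            _setting(k, "setting_distribution"): _prob(v, f"setting_distribution.{k}")
            for k, v in dist_raw.items()
        }
        overrides: dict[str, dict[Setting, CoverageSpec]] = {}
        for iv_id, by_setting in _expect_mapping(
            d.get("coverage_overrides", {}) or {}, "coverage_overrides"
        ).items():
            cp = f"coverage_overrides[{iv_id}]"
            overrides[iv_id] = {
                _setting(s, cp): CoverageSpec.from_dict(c, f"{cp}.{s}")
                for s, c in _expect_mapping(by_setting, cp).items()
            }
        births = d.get("births")
        if not isinstance(births, (int, float)) or isinstance(births, bool):
            raise ValidationError("births", f"expected a number, got {births!r}")
        transfer_overrides: dict[Setting, dict[Setting, float]] = {}
        for from_key, by_to in _expect_mapping(
            d.get("transfer_overrides", {}) or {}, "transfer_overrides"
        ).items():
            from_s = _setting(from_key, "transfer_overrides")
            tp = f"transfer_overrides.{from_s.value}"
            transfer_overrides[from_s] = {
                _setting(to_key, tp): _prob(p, f"{tp}.{to_key}")
                for to_key, p in _expect_mapping(by_to, tp).items()
            }
        bounds_raw = d.get("bounds")
        params = cls(
            scenario_id=_string(d.get("scenario_id"), "scenario_id"),
            births=float(births),
            setting_distribution=dist,
            coverage=resolve_coverage(model, overrides),
            coverage_overrides=overrides,
            transfer_overrides=transfer_overrides,
            bounds=None if bounds_raw is None else Bounds.from_dict(bounds_raw, "bounds"),
            mortality_adjustment=float(d.get("mortality_adjustment", 1.0)),
        )
        params.validate(model)
        return params


def effective_transfers_for(
    model: ModelDefinition,
    params: "ScenarioParameters",
    sub_id: str,
    from_setting: Setting,
) -> list[TransferRule]:
    """Model transfer rules for one (sub-condition, setting) with scenario
    overrides applied.

    An override for a (from, to) pair replaces the probability of a matching
    rule, or adds a rule applying to this sub-condition if none exists.
    """
    rules = list(model.transfers_for(sub_id, from_setting))
    overrides = dict(params.transfer_overrides.get(from_setting, {}))
    out: list[TransferRule] = []
    for rule in rules:
        if rule.to_setting in overrides:
            p = overrides.pop(rule.to_setting)
            out.append(
                TransferRule(
                    from_setting=rule.from_setting,
                    to_setting=rule.to_setting,
                    probability=p,
                    applicable_subcondition_ids=rule.applicable_subcondition_ids,
                )
            )
        else:
            out.append(rule)
    for to_setting in sorted(overrides, key=lambda s: s.rank):
        out.append(
            TransferRule(
                from_setting=from_setting,
                to_setting=to_setting,
                probability=overrides[to_setting],
                applicable_subcondition_ids=frozenset({sub_id}),
            )
        )
    return out


def resolve_coverage(
    model: ModelDefinition,
    overrides: Mapping[str, Mapping[Setting, CoverageSpec]],
) -> dict[str, dict[Setting, CoverageSpec]]:
    """Fill model coverage defaults, then apply scenario overrides.

    Overrides keyed by a bare intervention id apply to every entry sharing that
    id (dual-timing entries); overrides keyed by a full key apply to that entry
    alone.
    """
    resolved: dict[str, dict[Setting, CoverageSpec]] = {}
    for iv in model.interventions:
        per_setting = {s: iv.coverage_at(s) for s in SETTINGS}
        for ref in (iv.id, iv.key):
            if ref in overrides:
                per_setting.update(overrides[ref])
        resolved[iv.key] = per_setting
    return resolved


# -- file I/O ---------------------------------------------------------------


def _load_yaml(path: str | Path) -> Any:
    text = Path(path).read_text()
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(str(path), f"malformed file: {exc}") from exc


def load_model(path: str | Path) -> ModelDefinition:
    """Read and validate a model-definition file."""
    return ModelDefinition.from_dict(_load_yaml(path))


def save_model(model: ModelDefinition, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def load_scenario(path: str | Path, model: ModelDefinition) -> ScenarioParameters:
    """Read a scenario file and resolve it against ``model``."""
    return ScenarioParameters.from_dict(_load_yaml(path), model)


def save_scenario(params: ScenarioParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def copy_params(params: ScenarioParameters) -> ScenarioParameters:
    """Deep copy suitable for preset construction."""
    return copy.deepcopy(params)
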