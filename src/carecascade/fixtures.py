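"""Default model structure, demo scenarios, and seeded synthetic parameters.

The default model encodes the published condition/sub-condition structure
(maternal obstructed labor, infection, hemorrhage, hypertensive disorders and
fetal distress; neonatal infection, birth asphyxia and preterm birth) but all
numeric parameters are SYNTHETIC PLACEHOLDERS — the published parameter values
live in an unpublished data version and are deliberately not reproduced here.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .schema import (
    SETTINGS,
    Composition,
    CoverageSpec,
    InterventionKind,
    InterventionSpec,
    ModelDefinition,
    NeonatalLink,
    PopulationType,
    ScenarioParameters,
    Setting,
    SubConditionSpec,
    TransferRule,
    resolve_coverage,
)

__all__ = [
    "default_model",
    "default_scenario",
    "demo_ladder",
    "randomize_model",
    "generate_random_params",
    "random_configuration",
]


def _cov(home: tuple[float, float], clinic: tuple[float, float],
         hospital: tuple[float, float]) -> dict[Setting, CoverageSpec]:
    return {
        Setting.HOME: CoverageSpec(*home),
        Setting.CLINIC: CoverageSpec(*clinic),
        Setting.HOSPITAL: CoverageSpec(*hospital),
    }


_LINE = lambda order: Composition("line", order)  # noqa: E731


def _maternal(id_: str, condition: str, inc: float, cfr: float,
              treated_cfr: float = 0.0,
              fetal: tuple[float, float] | None = None,
              links: dict[str, NeonatalLink] | None = None) -> SubConditionSpec:
    return SubConditionSpec(
        id=id_,
        condition_id=condition,
        population=PopulationType.MATERNAL,
        unprevented_incidence=inc,
        untreated_cfr=cfr,
        treated_cfr=treated_cfr,
        fetal_death_rate_untreated=fetal[0] if fetal else None,
        fetal_death_rate_treated=fetal[1] if fetal else None,
        neonatal_links=links or {},
    )


def _neonatal(id_: str, condition: str, inc: float, cfr: float,
              treated_cfr: float = 0.0) -> SubConditionSpec:
    return SubConditionSpec(
        id=id_,
        condition_id=condition,
        population=PopulationType.NEONATAL,
        unprevented_incidence=inc,
        untreated_cfr=cfr,
        treated_cfr=treated_cfr,
    )


def default_model() -> ModelDefinition:
    """The default condition graph with synthetic placeholder parameters."""
    hemorrhage = "maternal_hemorrhage"
    infection = "maternal_infection"
    hypertension = "maternal_hypertensive_disorders"

    sub_conditions = [
        _maternal("obstructed_labor", "obstructed_labor", 0.05, 0.04,
                  fetal=(0.15, 0.03),
                  links={"birth_asphyxia": NeonatalLink(0.25, 0.05)}),
        _maternal("sepsis", infection, 0.03, 0.15, fetal=(0.10, 0.03),
                  links={"neonatal_sepsis": NeonatalLink(0.20, 0.05)}),
        _maternal("syphilis", infection, 0.02, 0.05, fetal=(0.25, 0.05)),
        _maternal("malaria", infection, 0.06, 0.03, fetal=(0.12, 0.04),
                  links={"preterm_birth": NeonatalLink(0.10, 0.05)}),
        _maternal("placental_abruption", hemorrhage, 0.010, 0.10, fetal=(0.30, 0.10)),
        _maternal("placenta_previa", hemorrhage, 0.005, 0.08, fetal=(0.25, 0.08)),
        _maternal("ruptured_uterus", hemorrhage, 0.002, 0.25, fetal=(0.40, 0.10)),
        _maternal("lacerations", hemorrhage, 0.020, 0.02),
        _maternal("atonic_uterus", hemorrhage, 0.050, 0.06),
        _maternal("retained_placenta", hemorrhage, 0.015, 0.04),
        _maternal("preeclampsia", hypertension, 0.035, 0.05, fetal=(0.10, 0.03),
                  links={"preterm_birth": NeonatalLink(0.15, 0.05),
                         "birth_asphyxia": NeonatalLink(0.10, 0.03)}),
        _maternal("eclampsia", hypertension, 0.015, 0.15, fetal=(0.20, 0.05),
                  links={"birth_asphyxia": NeonatalLink(0.20, 0.05),
                         "preterm_birth": NeonatalLink(0.20, 0.08)}),
        _maternal("fetal_distress", "fetal_distress", 0.04, 0.0, fetal=(0.20, 0.05),
                  links={"birth_asphyxia": NeonatalLink(0.30, 0.10)}),
        # figure-abbreviation leaf with zeroed placeholder parameters
        _maternal("iugr", "fetal_distress", 0.0, 0.0, fetal=(0.0, 0.0)),
        _neonatal("neonatal_sepsis", "neonatal_infection", 0.04, 0.20),
        _neonatal("birth_asphyxia", "birth_asphyxia", 0.03, 0.25),
        _neonatal("preterm_birth", "preterm_birth", 0.10, 0.12),
        # preterm complications shown only as abbreviations; zeroed placeholders
        _neonatal("rds", "preterm_birth", 0.0, 0.0),
        _neonatal("ivh", "preterm_birth", 0.0, 0.0),
        _neonatal("nec", "preterm_birth", 0.0, 0.0),
    ]

    hemorrhage_subs = frozenset(
        {"placental_abruption", "placenta_previa", "ruptured_uterus",
         "lacerations", "atonic_uterus", "retained_placenta"}
    )
    iv = InterventionSpec
    interventions = [
        # --- hemorrhage ---------------------------------------------------
        iv(id="oxytocin", kind=InterventionKind.PREVENTIVE,
           target_subcondition_ids=frozenset({"atonic_uterus"}), efficacy=0.50,
           coverage=_cov((0.05, 0.4), (0.45, 0.7), (0.85, 0.9)),
           timing_tags=frozenset({"prevention"})),
        iv(id="uterine_massage", kind=InterventionKind.PREVENTIVE,
           target_subcondition_ids=frozenset({"atonic_uterus"}), efficacy=0.30,
           coverage=_cov((0.20, 0.5), (0.50, 0.7), (0.80, 0.8))),
        iv(id="pph_recognition", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=hemorrhage_subs, efficacy=0.80,
           coverage=_cov((0.30, 0.6), (0.70, 0.8), (0.90, 0.95))),
        iv(id="oxytocin", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"atonic_uterus"}), efficacy=0.55,
           coverage=_cov((0.05, 0.4), (0.45, 0.7), (0.85, 0.9)),
           composition=_LINE(1), timing_tags=frozenset({"treatment"})),
        iv(id="balloon_tamponade", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"atonic_uterus"}), efficacy=0.60,
           coverage=_cov((0.0, 0.0), (0.20, 0.5), (0.60, 0.8)),
           composition=_LINE(2)),
        iv(id="blood_transfusion", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=hemorrhage_subs - {"atonic_uterus"},
           efficacy=0.70, fetal_efficacy=0.40,
           coverage=_cov((0.0, 0.0), (0.10, 0.5), (0.60, 0.8))),
        iv(id="manual_removal", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"retained_placenta"}), efficacy=0.75,
           coverage=_cov((0.05, 0.3), (0.50, 0.7), (0.85, 0.9))),
        iv(id="uterine_repair_surgery", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"ruptured_uterus"}), efficacy=0.80,
           fetal_efficacy=0.50, single_use=True,
           coverage=_cov((0.0, 0.0), (0.0, 0.0), (0.55, 0.85))),
        # --- infection ----------------------------------------------------
        iv(id="clean_delivery_practices", kind=InterventionKind.PREVENTIVE,
           target_subcondition_ids=frozenset({"sepsis"}), efficacy=0.40,
           coverage=_cov((0.25, 0.5), (0.60, 0.7), (0.85, 0.9))),
        iv(id="fever_recognition", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=frozenset({"sepsis", "malaria"}), efficacy=0.70,
           coverage=_cov((0.35, 0.6), (0.65, 0.8), (0.85, 0.9))),
        iv(id="antibiotics", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"sepsis"}), efficacy=0.85,
           fetal_efficacy=0.30, neonatal_efficacy=0.50,
           coverage=_cov((0.05, 0.4), (0.55, 0.75), (0.85, 0.9))),
        iv(id="syphilis_screening", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=frozenset({"syphilis"}), efficacy=0.85,
           coverage=_cov((0.0, 0.0), (0.45, 0.7), (0.75, 0.85))),
        iv(id="penicillin", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"syphilis"}), efficacy=0.90,
           fetal_efficacy=0.60,
           coverage=_cov((0.0, 0.0), (0.50, 0.75), (0.80, 0.9))),
        iv(id="bed_nets", kind=InterventionKind.PREVENTIVE,
           target_subcondition_ids=frozenset({"malaria"}), efficacy=0.50,
           coverage=_cov((0.35, 0.6), (0.40, 0.65), (0.45, 0.7))),
        iv(id="antimalarials", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"malaria"}), efficacy=0.85,
           fetal_efficacy=0.40, neonatal_efficacy=0.30,
           coverage=_cov((0.10, 0.5), (0.55, 0.75), (0.80, 0.85))),
        # --- obstructed labor / hypertension / fetal distress --------------
        iv(id="partograph", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=frozenset({"obstructed_labor"}), efficacy=0.75,
           coverage=_cov((0.0, 0.0), (0.40, 0.7), (0.80, 0.9))),
        iv(id="cesarean_delivery", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset(
               {"obstructed_labor", "preeclampsia", "eclampsia", "fetal_distress"}),
           efficacy=0.90, fetal_efficacy=0.70, neonatal_efficacy=0.60,
           single_use=True,
           coverage=_cov((0.0, 0.0), (0.0, 0.0), (0.50, 0.85))),
        iv(id="labor_induction", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"preeclampsia", "eclampsia"}),
           efficacy=0.50, fetal_efficacy=0.30, neonatal_efficacy=0.30,
           coverage=_cov((0.0, 0.0), (0.25, 0.6), (0.65, 0.8))),
        iv(id="mgso4", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"preeclampsia", "eclampsia"}),
           efficacy=0.60,
           coverage=_cov((0.0, 0.0), (0.15, 0.5), (0.55, 0.8))),
        iv(id="bp_screening", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=frozenset({"preeclampsia"}), efficacy=0.70,
           coverage=_cov((0.05, 0.4), (0.55, 0.75), (0.85, 0.9))),
        iv(id="seizure_recognition", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=frozenset({"eclampsia"}), efficacy=0.80,
           coverage=_cov((0.40, 0.6), (0.70, 0.8), (0.90, 0.95))),
        iv(id="fetal_monitoring", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=frozenset({"fetal_distress"}), efficacy=0.65,
           coverage=_cov((0.0, 0.0), (0.30, 0.6), (0.75, 0.85))),
        # --- neonatal -----------------------------------------------------
        iv(id="cord_care", kind=InterventionKind.PREVENTIVE,
           target_subcondition_ids=frozenset({"neonatal_sepsis"}), efficacy=0.30,
           coverage=_cov((0.25, 0.5), (0.55, 0.7), (0.80, 0.85))),
        iv(id="newborn_assessment", kind=InterventionKind.DIAGNOSTIC,
           target_subcondition_ids=frozenset(
               {"neonatal_sepsis", "birth_asphyxia", "preterm_birth"}),
           efficacy=0.70,
           coverage=_cov((0.20, 0.5), (0.60, 0.75), (0.85, 0.9))),
        iv(id="neonatal_antibiotics", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"neonatal_sepsis"}), efficacy=0.80,
           coverage=_cov((0.05, 0.3), (0.50, 0.7), (0.80, 0.9))),
        iv(id="bag_and_mask_resuscitation", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"birth_asphyxia"}), efficacy=0.65,
           coverage=_cov((0.05, 0.3), (0.45, 0.7), (0.80, 0.9))),
        iv(id="kangaroo_care", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"preterm_birth"}), efficacy=0.40,
           coverage=_cov((0.10, 0.4), (0.40, 0.6), (0.70, 0.8))),
        iv(id="oxygen_therapy", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"preterm_birth"}), efficacy=0.30,
           coverage=_cov((0.0, 0.0), (0.25, 0.55), (0.70, 0.8)),
           composition=_LINE(1)),
        iv(id="ventilation", kind=InterventionKind.TREATMENT,
           target_subcondition_ids=frozenset({"preterm_birth"}), efficacy=0.50,
           coverage=_cov((0.0, 0.0), (0.0, 0.0), (0.40, 0.7)),
           composition=_LINE(2)),
    ]

    all_subs = frozenset(s.id for s in sub_conditions)
    transfers = [
        TransferRule(Setting.HOME, Setting.CLINIC, 0.20, all_subs),
        TransferRule(Setting.HOME, Setting.HOSPITAL, 0.15, all_subs),
        TransferRule(Setting.CLINIC, Setting.HOSPITAL, 0.25, all_subs),
    ]
    model = ModelDefinition(
        sub_conditions=sub_conditions,
        interventions=interventions,
        transfers=transfers,
    )
    model.validate()
    return model


def default_scenario(
    model: ModelDefinition,
    scenario_id: str = "current_care",
    births: float = 1_000_000.0,
) -> ScenarioParameters:
    """Baseline scenario: model-default coverage, half of births at home."""
    params = ScenarioParameters(
        scenario_id=scenario_id,
        births=births,
        setting_distribution={
            Setting.HOME: 0.5, Setting.CLINIC: 0.3, Setting.HOSPITAL: 0.2
        },
        coverage=resolve_coverage(model, {}),
    )
    params.validate(model)
    return params


def demo_ladder(model: ModelDefinition) -> list[ScenarioParameters]:
    """Four-step bottleneck-decomposition demo for the anticonvulsant pathway.

    Step 1 scales the drug alone to full clinic/hospital coverage; step 2 adds
    universal diagnosis; step 3 adds delivery interventions; step 4 adds
    near-universal transfer to facility care.  All numbers are synthetic.
    """
    full = CoverageSpec(1.0, 1.0)
    full_ch = {Setting.CLINIC: full, Setting.HOSPITAL: full}
    full_all = {s: full for s in SETTINGS}

    steps: list[ScenarioParameters] = []
    overrides: dict[str, dict[Setting, CoverageSpec]] = {"mgso4": dict(full_ch)}
    steps.append(_with_overrides(model, "ladder_1_drug_only", overrides))

    overrides = {
        "mgso4": dict(full_ch),
        "bp_screening": dict(full_all),
        "seizure_recognition": dict(full_all),
    }
    steps.append(_with_overrides(model, "ladder_2_plus_diagnosis", overrides))

    overrides = dict(overrides)
    overrides["cesarean_delivery"] = {Setting.HOSPITAL: full}
    overrides["labor_induction"] = dict(full_ch)
    steps.append(_with_overrides(model, "ladder_3_plus_delivery", overrides))

    step4 = _with_overrides(model, "ladder_4_plus_transfer", dict(overrides))
    step4.transfer_overrides = {
        Setting.HOME: {Setting.CLINIC: 0.1, Setting.HOSPITAL: 0.9},
        Setting.CLINIC: {Setting.HOSPITAL: 0.9},
    }
    step4.validate(model)
    steps.append(step4)
    return steps


def _with_overrides(
    model: ModelDefinition,
    scenario_id: str,
    overrides: dict[str, dict[Setting, CoverageSpec]],
) -> ScenarioParameters:
    params = ScenarioParameters(
        scenario_id=scenario_id,
        births=1_000_000.0,
        setting_distribution={
            Setting.HOME: 0.5, Setting.CLINIC: 0.3, Setting.HOSPITAL: 0.2
        },
        coverage=resolve_coverage(model, overrides),
        coverage_overrides=overrides,
    )
    params.validate(model)
    return params


# -- seeded synthetic generators --------------------------------------------


def randomize_model(seed: int, model: ModelDefinition | None = None) -> ModelDefinition:
    """Copy of ``model`` (default structure) with randomized rates.

    Draws incidences, CFRs (treated <= untreated), fetal rates, neonatal link
    rates, efficacies and transfer probabilities from uniform ranges.
    Deterministic per seed; every output passes full validation.
    """
    base = model if model is not None else default_model()
    rng = np.random.default_rng([seed, 101])

    subs = []
    for sub in base.sub_conditions:
        inc = rng.uniform(0.01, 0.30)
        cfr = rng.uniform(0.05, 0.50)
        treated_cfr = cfr * rng.uniform(0.0, 0.5)
        fetal = None
        if sub.fetal_death_rate_untreated is not None:
            fu = rng.uniform(0.0, 0.40)
            fetal = (fu, fu * rng.uniform(0.0, 1.0))
        links = {}
        for neo_id in sub.neonatal_links:
            lu = rng.uniform(0.0, 0.30)
            links[neo_id] = NeonatalLink(lu, lu * rng.uniform(0.0, 1.0))
        subs.append(
            dataclasses.replace(
                sub,
                unprevented_incidence=inc,
                untreated_cfr=cfr,
                treated_cfr=treated_cfr,
                fetal_death_rate_untreated=fetal[0] if fetal else None,
                fetal_death_rate_treated=fetal[1] if fetal else None,
                neonatal_links=links,
            )
        )

    interventions = []
    for iv in base.interventions:
        interventions.append(
            dataclasses.replace(
                iv,
                efficacy=rng.uniform(0.2, 0.95),
                fetal_efficacy=(
                    None if iv.fetal_efficacy is None else rng.uniform(0.0, 1.0)
                ),
                neonatal_efficacy=(
                    None if iv.neonatal_efficacy is None else rng.uniform(0.0, 1.0)
                ),
            )
        )

    all_subs = frozenset(s.id for s in subs)
    t_home = rng.uniform(0.0, 0.9)
    w = rng.uniform(0.0, 1.0)
    transfers = [
        TransferRule(Setting.HOME, Setting.CLINIC, t_home * w, all_subs),
        TransferRule(Setting.HOME, Setting.HOSPITAL, t_home * (1.0 - w), all_subs),
        TransferRule(Setting.CLINIC, Setting.HOSPITAL, rng.uniform(0.0, 0.9), all_subs),
    ]
    out = ModelDefinition(
        sub_conditions=subs, interventions=interventions, transfers=transfers
    )
    out.validate()
    return out


def generate_random_params(seed: int, model: ModelDefinition) -> ScenarioParameters:
    """Random valid ScenarioParameters for ``model``; deterministic per seed.

    Per-setting penetration/utilization are drawn ORDERED up the care ladder
    (home <= clinic <= hospital), matching the structure of real coverage data
    and preserving the model's transfer monotonicity property.
    """
    rng = np.random.default_rng([seed, 202])
    dist = rng.dirichlet([2.0, 2.0, 2.0])
    overrides: dict[str, dict[Setting, CoverageSpec]] = {}
    for iv in model.interventions:
        pens = np.sort(rng.uniform(0.0, 1.0, size=3))
        utils = np.sort(rng.uniform(0.0, 1.0, size=3))
        overrides[iv.key] = {
            s: CoverageSpec(float(pens[i]), float(utils[i]))
            for i, s in enumerate(SETTINGS)
        }
    params = ScenarioParameters(
        scenario_id=f"random_{seed}",
        births=float(rng.integers(100_000, 1_000_000)),
        setting_distribution={s: float(dist[i]) for i, s in enumerate(SETTINGS)},
        coverage=resolve_coverage(model, overrides),
        coverage_overrides=overrides,
    )
    params.validate(model)
    return params


def random_configuration(seed: int) -> tuple[ModelDefinition, ScenarioParameters]:
    """A seeded random (model, params) pair over the default structure."""
    model = randomize_model(seed)
    return model, generate_random_params(seed, model)
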