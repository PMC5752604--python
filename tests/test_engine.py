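"""Tests for the deterministic cohort engine."""

from __future__ import annotations

import copy
import dataclasses

import pytest

from carecascade import engine, fixtures, scenarios
from carecascade.engine import (
    CohortStratum,
    apply_diagnosis,
    apply_prevention,
    apply_transfer,
    apply_treatment,
    compute_mortality,
    initial_strata,
    propagate_neonatal,
    run_subcondition,
    trace_to_frame,
)
from carecascade.errors import ConfigurationError
from carecascade.schema import (
    SETTINGS,
    CoverageSpec,
    InterventionKind,
    InterventionSpec,
    ModelDefinition,
    NeonatalLink,
    PopulationType,
    Setting,
    SubConditionSpec,
    TransferRule,
)

from conftest import make_simple_model, make_simple_params


def _stratum(mass, setting=Setting.HOME, **kwargs):
    return CohortStratum(mass=mass, setting=setting, **kwargs)


class TestInitialStrata:
    def test_masses(self, params):
        params.births = 1000.0
        masses = [s.mass for s in initial_strata(params)]
        assert masses == pytest.approx([500.0, 300.0, 200.0])

    def test_zero_births(self, params):
        params.births = 0.0
        assert all(s.mass == 0.0 for s in initial_strata(params))

    def test_conservation(self, params):
        assert sum(s.mass for s in initial_strata(params)) == pytest.approx(
            params.births
        )


_SUB = SubConditionSpec(
    id="s", condition_id="c", population=PopulationType.MATERNAL,
    unprevented_incidence=0.1, untreated_cfr=0.02,
)


class TestApplyPrevention:
    def test_arithmetic(self):
        positive, negative = apply_prevention(_stratum(1000.0), _SUB, 0.3)
        assert positive.mass == pytest.approx(70.0)
        assert negative.mass == pytest.approx(930.0)
        assert positive.condition_positive and not negative.condition_positive

    def test_perfect_prevention(self):
        positive, _ = apply_prevention(_stratum(1000.0), _SUB, 1.0)
        assert positive.mass == 0.0

    def test_no_intervention_limit(self):
        positive, _ = apply_prevention(_stratum(1000.0), _SUB, 0.0)
        assert positive.mass == pytest.approx(1000.0 * _SUB.unprevented_incidence)


class TestApplyDiagnosis:
    def test_split(self):
        positive = _stratum(70.0, condition_positive=True)
        diagnosed, undiagnosed = apply_diagnosis(positive, 0.5)
        assert diagnosed.mass == pytest.approx(35.0)
        assert undiagnosed.mass == pytest.approx(35.0)
        assert diagnosed.diagnosed and not undiagnosed.diagnosed

    def test_zero_diagnosis_gates_everything(self):
        positive = _stratum(70.0, condition_positive=True)
        diagnosed, undiagnosed = apply_diagnosis(positive, 0.0)
        assert diagnosed.mass == 0.0
        assert undiagnosed.mass == pytest.approx(70.0)

    def test_condition_negative_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_diagnosis(_stratum(10.0, condition_positive=False), 0.5)


class TestApplyTransfer:
    def test_split(self):
        diagnosed = _stratum(100.0, condition_positive=True, diagnosed=True)
        rule = TransferRule(Setting.HOME, Setting.HOSPITAL, 0.6, frozenset({"s"}))
        out = apply_transfer(diagnosed, [rule])
        by_setting = {s.setting: s.mass for s in out}
        assert by_setting[Setting.HOSPITAL] == pytest.approx(60.0)
        assert by_setting[Setting.HOME] == pytest.approx(40.0)

    def test_no_rules_identity(self):
        diagnosed = _stratum(100.0, condition_positive=True, diagnosed=True)
        out = apply_transfer(diagnosed, [])
        assert len(out) == 1 and out[0].mass == 100.0

    def test_conservation(self):
        diagnosed = _stratum(100.0, condition_positive=True, diagnosed=True)
        rules = [
            TransferRule(Setting.HOME, Setting.CLINIC, 0.3, frozenset({"s"})),
            TransferRule(Setting.HOME, Setting.HOSPITAL, 0.4, frozenset({"s"})),
        ]
        assert sum(s.mass for s in apply_transfer(diagnosed, rules)) == pytest.approx(100.0)

    def test_overflow_rejected(self):
        diagnosed = _stratum(100.0, condition_positive=True, diagnosed=True)
        rules = [
            TransferRule(Setting.HOME, Setting.CLINIC, 0.7, frozenset({"s"})),
            TransferRule(Setting.HOME, Setting.HOSPITAL, 0.5, frozenset({"s"})),
        ]
        with pytest.raises(ConfigurationError):
            apply_transfer(diagnosed, rules)


class TestApplyTreatment:
    def test_split(self):
        diagnosed = _stratum(60.0, condition_positive=True, diagnosed=True)
        treated, failed = apply_treatment(diagnosed, 0.8)
        assert treated.mass == pytest.approx(48.0)
        assert failed.mass == pytest.approx(12.0)

    @pytest.mark.parametrize("p,expect", [(0.0, 0.0), (1.0, 60.0)])
    def test_limits(self, p, expect):
        diagnosed = _stratum(60.0, condition_positive=True, diagnosed=True)
        treated, _ = apply_treatment(diagnosed, p)
        assert treated.mass == pytest.approx(expect)

    def test_undiagnosed_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_treatment(_stratum(10.0, condition_positive=True, diagnosed=False), 0.5)


class TestComputeMortality:
    def test_closed_form(self):
        strata = [_stratum(1000.0, condition_positive=True, diagnosed=False)]
        deaths, fetal = compute_mortality(strata, _SUB)
        assert deaths == pytest.approx(20.0)
        assert fetal == 0.0

    def test_all_treated_zero_cfr(self):
        strata = [
            _stratum(100.0, condition_positive=True, diagnosed=True,
                     treated_successfully=True)
        ]
        assert compute_mortality(strata, _SUB)[0] == 0.0

    def test_mixed_strata_hand_arithmetic(self):
        # 48 treated (cfr 0) + 12 failed + 35 undiagnosed at cfr 0.02 -> 0.94
        strata = [
            _stratum(48.0, condition_positive=True, diagnosed=True,
                     treated_successfully=True),
            _stratum(12.0, condition_positive=True, diagnosed=True,
                     treated_successfully=False),
            _stratum(35.0, condition_positive=True, diagnosed=False),
        ]
        assert compute_mortality(strata, _SUB)[0] == pytest.approx(0.94)

    def test_fetal_rates_with_survival_factor(self):
        sub = dataclasses.replace(
            _SUB, fetal_death_rate_untreated=0.2, fetal_death_rate_treated=0.1
        )
        strata = [
            _stratum(100.0, condition_positive=True, diagnosed=True,
                     treated_successfully=True, fetal_survival_factor=0.5),
            _stratum(50.0, condition_positive=True, diagnosed=False),
        ]
        _, fetal = compute_mortality(strata, sub)
        assert fetal == pytest.approx(100 * 0.1 * 0.5 + 50 * 0.2)


class TestRunSubcondition:
    def test_no_intervention_closed_form(self, model, params):
        bare = scenarios.preset_no_intervention(params)
        for sub in model.maternal_subconditions:
            result = run_subcondition(sub, model, bare)
            expect = bare.births * sub.unprevented_incidence * sub.untreated_cfr
            assert result.maternal_deaths == pytest.approx(expect, rel=1e-12)

    def test_perfect_prevention(self):
        model = make_simple_model(preventive_efficacy=1.0)
        params = make_simple_params(model)
        result = run_subcondition(model.sub_conditions[0], model, params)
        assert result.cases == 0.0
        assert result.maternal_deaths == 0.0

    def test_treatment_requires_diagnosis(self):
        # a treatment with full coverage saves nobody without a diagnostic
        model = make_simple_model(treatment_efficacy=1.0)
        params = make_simple_params(model)
        result = run_subcondition(model.sub_conditions[0], model, params)
        expect = params.births * 0.1 * 0.02
        assert result.maternal_deaths == pytest.approx(expect)

    def test_diagnosed_and_treated(self):
        model = make_simple_model(diagnostic_efficacy=1.0, treatment_efficacy=0.8)
        params = make_simple_params(model)
        result = run_subcondition(model.sub_conditions[0], model, params)
        cases = params.births * 0.1
        assert result.cases == pytest.approx(cases)
        assert result.maternal_deaths == pytest.approx(cases * 0.2 * 0.02)

    def test_mass_conservation_in_trace(self, model, params):
        for sub in model.sub_conditions:
            result = run_subcondition(sub, model, params)
            frame = trace_to_frame(result)
            initial = frame.loc[frame.step == "initial", "mass"].sum()
            prevention = frame.loc[
                frame.step.str.startswith("prevention"), "mass"
            ].sum()
            assert prevention == pytest.approx(initial, rel=1e-9)

    def test_administered_tallies_present(self, model, params):
        result = run_subcondition(model.subcondition("atonic_uterus"), model, params)
        assert "oxytocin@prevention" in result.interventions_administered
        assert "oxytocin@treatment" in result.interventions_administered
        assert all(v >= 0 for v in result.interventions_administered.values())

    def test_deaths_bounded_by_cases(self, model, params):
        for sub in model.sub_conditions:
            result = run_subcondition(sub, model, params)
            assert result.deaths <= result.cases + 1e-9
            assert result.fetal_deaths <= result.cases + 1e-9


class TestPropagateNeonatal:
    def _linked_model(self, neonatal_efficacy):
        maternal = SubConditionSpec(
            id="pre", condition_id="hyp", population=PopulationType.MATERNAL,
            unprevented_incidence=0.1, untreated_cfr=0.05,
            neonatal_links={"asphyxia": NeonatalLink(0.3, 0.3)},
        )
        neonatal = SubConditionSpec(
            id="asphyxia", condition_id="asphyxia",
            population=PopulationType.NEONATAL,
            unprevented_incidence=0.0, untreated_cfr=0.25,
        )
        cov = {s: CoverageSpec(1.0, 1.0) for s in SETTINGS}
        interventions = [
            InterventionSpec(
                id="diagnose", kind=InterventionKind.DIAGNOSTIC,
                target_subcondition_ids=frozenset({"pre"}), efficacy=1.0,
                coverage=dict(cov),
            ),
            InterventionSpec(
                id="delivery", kind=InterventionKind.TREATMENT,
                target_subcondition_ids=frozenset({"pre"}), efficacy=1.0,
                neonatal_efficacy=neonatal_efficacy, coverage=dict(cov),
            ),
        ]
        m = ModelDefinition(
            sub_conditions=[maternal, neonatal], interventions=interventions,
            transfers=[],
        )
        m.validate()
        return m

    def test_perfect_neonatal_benefit(self):
        model = self._linked_model(neonatal_efficacy=1.0)
        params = make_simple_params(model)
        result = run_subcondition(model.subcondition("pre"), model, params)
        # everyone diagnosed and treated; neonatal efficacy 1 zeroes the link
        assert result.neonatal_incidence_contributions["asphyxia"] == pytest.approx(0.0)

    def test_zero_neonatal_benefit_matches_untreated_rate(self):
        model = self._linked_model(neonatal_efficacy=0.0)
        params = make_simple_params(model)
        result = run_subcondition(model.subcondition("pre"), model, params)
        expect = params.births * 0.1 * 0.3  # all cases at the link rate
        assert result.neonatal_incidence_contributions["asphyxia"] == pytest.approx(expect)

    def test_contribution_bounded_by_cases(self, model, params):
        for sub in model.maternal_subconditions:
            result = run_subcondition(sub, model, params)
            for mass in result.neonatal_incidence_contributions.values():
                assert mass <= result.cases + 1e-9

    def test_aggregation(self, model, params):
        results = [
            run_subcondition(sub, model, params)
            for sub in model.maternal_subconditions
        ]
        pooled = propagate_neonatal(results, model)
        for res in results:
            for neo_id, total in res.neonatal_incidence_contributions.items():
                assert sum(pooled[neo_id].values()) >= total - 1e-9

    def test_unknown_link_target_rejected(self, model):
        fake = engine.SubConditionResult(
            subcondition_id="x", population=PopulationType.MATERNAL,
            cases=1.0, maternal_deaths=0.0, fetal_deaths=0.0, neonatal_deaths=0.0,
            neonatal_incidence_contributions={"nope": 1.0},
            contributions_by_setting={"nope": {s: 0.0 for s in SETTINGS}},
            interventions_administered={},
        )
        with pytest.raises(ConfigurationError):
            propagate_neonatal([fake], model)


class TestGating:
    def test_zero_diagnosis_equals_zero_treatment(self, model, params):
        no_diag = copy.deepcopy(params)
        no_treat = copy.deepcopy(params)
        for iv in model.interventions:
            zero = CoverageSpec(0.0, 0.0)
            if iv.kind is InterventionKind.DIAGNOSTIC:
                no_diag.coverage[iv.key] = {s: zero for s in SETTINGS}
            if iv.kind is InterventionKind.TREATMENT:
                no_treat.coverage[iv.key] = {s: zero for s in SETTINGS}
        a = scenarios.run_scenario(model, no_diag)
        b = scenarios.run_scenario(model, no_treat)
        for key in a.deaths:
            assert a.deaths[key] == pytest.approx(b.deaths[key], rel=1e-12)


class TestMonotonicitySample:
    def test_increasing_coverage_never_raises_deaths(self):
        import numpy as np

        for seed in range(20):
            model, params = fixtures.random_configuration(seed)
            rng = np.random.default_rng([seed, 5])
            base = sum(scenarios.run_scenario(model, params).totals.values())
            bumped = copy.deepcopy(params)
            iv = model.interventions[rng.integers(len(model.interventions))]
            s = SETTINGS[rng.integers(3)]
            c = bumped.coverage[iv.key][s]
            bumped.coverage[iv.key][s] = CoverageSpec(
                min(1.0, c.penetration + 0.2), c.utilization
            )
            after = sum(scenarios.run_scenario(model, bumped).totals.values())
            assert after <= base + 1e-9 * max(1.0, base)
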