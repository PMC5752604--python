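# carecascade

A deterministic decision-tree cohort model of maternal, fetal, and neonatal
mortality interventions across home / clinic / hospital care settings.

An annual cohort of pregnancies is propagated, per cause-specific
sub-condition, through

```
incidence → prevention → diagnosis → transfer → treatment → mortality
```

on expected-count masses (no stochastic variation).  Interventions are
described by three constructs — **penetration** (availability), **utilization**
(appropriate use when available), and **efficacy** (benefit under ideal
conditions; setting-independent) — and compose either as order-free **layers**
(`1 − ∏(1 − sᵢ)`) or as ordered **lines**, where line *k* is only given to
patients who received and failed line *k − 1*.  Diagnosis gates both treatment
and upward transfer; maternal sub-conditions additionally drive fetal deaths
and linked neonatal-condition incidence.  Comparing two scenarios on the same
cohort yields lives saved per sub-condition and population, exposing which
step of the care cascade (drug, diagnosis, facility care, transfer) is the
binding bottleneck.

The shipped default model encodes the standard condition structure (maternal
obstructed labor, infection, hemorrhage, hypertensive disorders, fetal
distress; neonatal infection, birth asphyxia, preterm birth) with **synthetic
placeholder parameters** — it demonstrates the machinery and is not a source
of real-world estimates.

## Library quick start

```python
from carecascade import fixtures, scenarios

model = fixtures.default_model()
params = fixtures.default_scenario(model)

current = scenarios.run_scenario(model, params)
baseline = scenarios.run_scenario(model, scenarios.preset_no_intervention(params))
saved = scenarios.lives_saved(baseline, current)
print(current.totals, saved["by_population"])
```

Every run is deterministic (bit-identical for identical inputs) and embeds
content hashes of the model and scenario.  A seeded individual-level Monte
Carlo oracle (`carecascade.microsim`) re-implements the same decision rules by
explicit per-individual event sequencing and is used to verify the analytic
engine to within 4 binomial standard errors.

## Command line

```bash
carecascade validate --model fixtures/model_default.yaml \
                     --scenario fixtures/scenario_current_care.yaml

carecascade run --model fixtures/model_default.yaml \
                --scenario fixtures/scenario_no_intervention.yaml \
                --out results/no_intervention.csv

carecascade compare --model fixtures/model_default.yaml \
                    --reference fixtures/scenario_no_intervention.yaml \
                    --comparison fixtures/scenario_high_income.yaml \
                    --out results/lives_saved.csv

carecascade calibrate --model fixtures/model_default.yaml \
                      --targets fixtures/calibration_targets_example.yaml \
                      --out results/calibrated.csv

carecascade verify --seeds 20 --n 100000   # analytic engine vs microsim oracle
```

`fixtures/` also contains a four-step demo ladder
(`scenario_ladder_1_drug_only.yaml` … `scenario_ladder_4_plus_transfer.yaml`)
showing how scaling a drug alone, then adding diagnosis, delivery
interventions, and transfers, progressively unlocks lives saved.

File formats are documented in `docs/file-formats.md`.

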