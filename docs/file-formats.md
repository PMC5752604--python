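# File formats

Both input files are YAML with a `schema_version` gate (currently `"1.0"`;
any other value is rejected).  All probabilities are decimals in `[0, 1]`,
never percentages.  Loading always validates; error messages carry the dotted
path of the offending field.

## Model definition

Describes the condition graph, the intervention catalogue, and transfer rules.

```yaml
schema_version: "1.0"

sub_conditions:            # one entry per cause-specific etiology
  - id: atonic_uterus      # unique string
    condition_id: maternal_hemorrhage   # parent condition (free grouping label)
    population: maternal   # maternal | neonatal (fetal outcomes are derived,
                           # never a sub-condition population)
    unprevented_incidence: 0.05   # P(condition | no preventive intervention)
    untreated_cfr: 0.06    # P(death | condition, no successful treatment)
    treated_cfr: 0.0       # P(death | successful treatment); <= untreated_cfr
    # maternal sub-conditions only; both given or both omitted:
    fetal_death_rate_untreated: 0.15
    fetal_death_rate_treated: 0.03      # <= untreated rate
    # maternal sub-conditions only; incremental neonatal-condition incidence:
    neonatal_links:
      birth_asphyxia: {untreated: 0.25, treated: 0.05}   # treated <= untreated

interventions:
  - id: oxytocin
    kind: preventive       # preventive | diagnostic | treatment
    targets: [atonic_uterus]
    efficacy: 0.5          # one setting-independent value
    fetal_efficacy: 0.4    # optional, treatments only: extra fetal benefit
    neonatal_efficacy: 0.3 # optional: reduction of linked neonatal incidence
    composition: {mode: layer}          # or {mode: line, order: 1}
    single_use: false      # e.g. true for cesarean delivery
    timing_tags: [prevention]  # lets the same id appear at another stage
    coverage:              # per-setting defaults; missing settings mean (0, 0)
      home:     {penetration: 0.05, utilization: 0.4}
      clinic:   {penetration: 0.45, utilization: 0.7}
      hospital: {penetration: 0.85, utilization: 0.9}

transfers:                 # movement of diagnosed patients, strictly up-ladder
  - from: home             # home < clinic < hospital
    to: clinic
    probability: 0.2       # P(move | positive diagnosis at `from`)
    applies_to: [atonic_uterus, sepsis]
```

Validation rules (each has a failing test):

- every referenced id resolves; sub-condition ids are unique
- duplicate intervention ids are allowed only with distinct `timing_tags`
  (the internal key becomes `id@tag`)
- `line` orders within one (sub-condition, kind) group are unique and
  contiguous from 1
- `treated_cfr <= untreated_cfr`, `fetal_death_rate_treated <=
  fetal_death_rate_untreated`, link `treated <= untreated`
- neonatal sub-conditions carry no fetal rates and no neonatal links
- transfer rules move strictly up the ladder and outgoing probabilities per
  (setting, sub-condition) sum to at most 1

## Scenario parameters

```yaml
schema_version: "1.0"
scenario_id: current_care
births: 1000000            # pregnancies in the modeled time frame
setting_distribution:      # must sum to 1 (within 1e-9)
  home: 0.5
  clinic: 0.3
  hospital: 0.2
mortality_adjustment: 1.0  # optional scalar on reported deaths (default 1)

coverage_overrides:        # optional; replaces model coverage defaults
  mgso4:                   # bare id applies to every entry sharing the id
    clinic:   {penetration: 1.0, utilization: 1.0}
    hospital: {penetration: 1.0, utilization: 1.0}

transfer_overrides:        # optional; replace/add up-ladder transfer rates
  home:
    clinic: 0.1
    hospital: 0.9

bounds:                    # optional low/high sensitivity variants
  low:
    rate_overrides:
      sepsis: {unprevented_incidence: 0.02, untreated_cfr: 0.10}
    coverage_overrides:
      antibiotics:
        hospital: {penetration: 0.95, utilization: 0.95}
  high:
    rate_overrides:
      sepsis: {unprevented_incidence: 0.05, untreated_cfr: 0.25}
```

A loaded scenario is fully resolved: every intervention key has an effective
(penetration, utilization) per setting.  Writing a scenario re-emits only the
stated overrides, so write-then-load round-trips field for field.

## Output CSVs

- `run`: `scenario_id, subcondition, population, deaths, cases, low, high`
  (one `__total__` row per population; `low`/`high` filled when `--bounds`).
- `compare`: `reference, comparison, subcondition, population, lives_saved`.
- `--trace`: `subcondition, step, setting, condition_positive, diagnosed,
  treated_successfully, mass` — one row per stratum per decision-tree step.
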