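schema_version: '1.0'
scenario_id: current_care_with_bounds
births: 1000000.0
setting_distribution:
  home: 0.5
  clinic: 0.3
  hospital: 0.2
bounds:
  low:
    rate_overrides:
      sepsis:
        unprevented_incidence: 0.02
        untreated_cfr: 0.1
    coverage_overrides:
      antibiotics:
        hospital:
          penetration: 0.95
          utilization: 0.95
  high:
    rate_overrides:
      sepsis:
        unprevented_incidence: 0.05
        untreated_cfr: 0.25
    coverage_overrides:
      antibiotics:
        home:
          penetration: 0.0
          utilization: 0.0
        clinic:
          penetration: 0.2
          utilization: 0.4
        hospital:
          penetration: 0.5
          utilization: 0.6
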