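schema_version: '1.0'
scenario_id: ladder_2_plus_diagnosis
births: 1000000.0
setting_distribution:
  home: 0.5
  clinic: 0.3
  hospital: 0.2
coverage_overrides:
  bp_screening:
    home:
      penetration: 1.0
      utilization: 1.0
    clinic:
      penetration: 1.0
      utilization: 1.0
    hospital:
      penetration: 1.0
      utilization: 1.0
  mgso4:
    clinic:
      penetration: 1.0
      utilization: 1.0
    hospital:
      penetration: 1.0
      utilization: 1.0
  seizure_recognition:
    home:
      penetration: 1.0
      utilization: 1.0
    clinic:
      penetration: 1.0
      utilization: 1.0
    hospital:
      penetration: 1.0
      utilization: 1.0
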