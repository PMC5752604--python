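schema_version: '1.0'
scenario_id: current_care
births: 1000000.0
setting_distribution:
  home: 0.5
  clinic: 0.3
  hospital: 0.2
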