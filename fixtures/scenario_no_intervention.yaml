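schema_version: '1.0'
scenario_id: no_intervention
births: 1000000.0
setting_distribution:
  home: 0.5
  clinic: 0.3
  hospital: 0.2
coverage_overrides:
  antibiotics:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  antimalarials:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  bag_and_mask_resuscitation:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  balloon_tamponade:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  bed_nets:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  blood_transfusion:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  bp_screening:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  cesarean_delivery:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  clean_delivery_practices:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  cord_care:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  fetal_monitoring:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  fever_recognition:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  kangaroo_care:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  labor_induction:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  manual_removal:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  mgso4:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  neonatal_antibiotics:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  newborn_assessment:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  oxygen_therapy:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  oxytocin@prevention:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  oxytocin@treatment:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  partograph:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  penicillin:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  pph_recognition:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  seizure_recognition:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  syphilis_screening:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  uterine_massage:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  uterine_repair_surgery:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
  ventilation:
    home:
      penetration: 0.0
      utilization: 0.0
    clinic:
      penetration: 0.0
      utilization: 0.0
    hospital:
      penetration: 0.0
      utilization: 0.0
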