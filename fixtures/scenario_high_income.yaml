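schema_version: '1.0'
scenario_id: high_income
births: 1000000.0
setting_distribution:
  home: 0.5
  clinic: 0.3
  hospital: 0.2
coverage_overrides:
  antibiotics:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  antimalarials:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  bag_and_mask_resuscitation:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  balloon_tamponade:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  bed_nets:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  blood_transfusion:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  bp_screening:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  cesarean_delivery:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  clean_delivery_practices:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  cord_care:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  fetal_monitoring:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  fever_recognition:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  kangaroo_care:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  labor_induction:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  manual_removal:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  mgso4:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  neonatal_antibiotics:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  newborn_assessment:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  oxygen_therapy:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  oxytocin@prevention:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  oxytocin@treatment:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  partograph:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  penicillin:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  pph_recognition:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  seizure_recognition:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  syphilis_screening:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  uterine_massage:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  uterine_repair_surgery:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
  ventilation:
    clinic:
      penetration: 0.95
      utilization: 0.95
    hospital:
      penetration: 0.95
      utilization: 0.95
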