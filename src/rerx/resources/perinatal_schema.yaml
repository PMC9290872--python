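# Packaged 52-variable perinatal cohort schema.
#
# Outcome: emergency cesarean section (class 1, positive) vs vaginal delivery
# or elective cesarean (class 2, negative).
#
# Count-valued obstetric-history variables (gravida, parity, spontaneous
# abortions, prior cesareans, prior preterm births) are declared continuous:
# interpretable rule sets in this domain threshold them at fractional cut
# points (e.g. prior_cs > 0.32), implying a continuous treatment upstream.
name: perinatal52
variables:
  # --- maternal characteristics -------------------------------------------
  - {name: maternal_age,        kind: continuous, domain: [14, 60],    units: years}
  - {name: maternal_weight,     kind: continuous, domain: [30, 150],   units: kg}
  - {name: maternal_height,     kind: continuous, domain: [120, 200],  units: cm}
  - {name: bmi,                 kind: continuous, domain: [12, 50],    units: "kg/m^2"}
  - {name: gravida,             kind: continuous, domain: [0, 20],     units: count}
  - {name: parity,              kind: continuous, domain: [0, 20],     units: count}
  - {name: spontaneous_abortion, kind: continuous, domain: [0, 10],    units: count}
  - {name: infertility_treatment, kind: discrete, domain: [0, 1]}
  - {name: smoking,             kind: discrete,   domain: [0, 1]}
  - {name: alcohol,             kind: discrete,   domain: [0, 1]}
  # --- family history ------------------------------------------------------
  - {name: family_hypertension, kind: discrete,   domain: [0, 1]}
  - {name: family_diabetes,     kind: discrete,   domain: [0, 1]}
  # --- maternal history ----------------------------------------------------
  - {name: hyperthyroidism,     kind: discrete,   domain: [0, 1]}
  - {name: hypothyroidism,      kind: discrete,   domain: [0, 1]}
  - {name: overt_dm,            kind: discrete,   domain: [0, 1]}
  - {name: chronic_hypertension, kind: discrete,  domain: [0, 1]}
  - {name: hepatitis,           kind: discrete,   domain: [0, 1]}
  - {name: respiratory_disease, kind: discrete,   domain: [0, 1]}
  - {name: autoimmune_disease,  kind: discrete,   domain: [0, 1]}
  - {name: collagen_disease,    kind: discrete,   domain: [0, 1]}
  - {name: appendicitis,        kind: discrete,   domain: [0, 1]}
  - {name: cns_disease,         kind: discrete,   domain: [0, 1]}
  - {name: mental_disease,      kind: discrete,   domain: [0, 1]}
  - {name: renal_disease,       kind: discrete,   domain: [0, 1]}
  - {name: hematologic_disease, kind: discrete,   domain: [0, 1]}
  - {name: myoma,               kind: discrete,   domain: [0, 1]}
  - {name: uterine_operation,   kind: discrete,   domain: [0, 1]}
  # --- obstetric history ---------------------------------------------------
  - {name: prior_cs,            kind: continuous, domain: [0, 10],     units: count}
  - {name: gestational_hypertension_history, kind: discrete, domain: [0, 1]}
  - {name: preeclampsia_history, kind: discrete,  domain: [0, 1]}
  - {name: preterm_birth,       kind: continuous, domain: [0, 10],     units: count}
  - {name: premature_labor_history, kind: discrete, domain: [0, 1]}
  - {name: cervical_laceration_history, kind: discrete, domain: [0, 1]}
  - {name: placenta_abruption_history, kind: discrete, domain: [0, 1]}
  - {name: infection_history,   kind: discrete,   domain: [0, 1]}
  - {name: gdm_history,         kind: discrete,   domain: [0, 1]}
  - {name: prior_vaginal_delivery, kind: discrete, domain: [0, 1]}
  - {name: prior_vacuum_delivery, kind: discrete, domain: [0, 1]}
  # --- current pregnancy ---------------------------------------------------
  - {name: gestational_age,     kind: continuous, domain: [36, 43],    units: weeks}
  - {name: augmentation_of_labor, kind: discrete, domain: [0, 1]}
  - {name: fetal_growth_restriction, kind: discrete, domain: [0, 1]}
  - {name: induction_of_labor,  kind: discrete,   domain: [0, 1]}
  - {name: hdp,                 kind: discrete,   domain: [0, 1]}
  - {name: stillbirth_history,  kind: discrete,   domain: [0, 1]}
  - {name: torch_syndrome,      kind: discrete,   domain: [0, 1]}
  - {name: gdm,                 kind: discrete,   domain: [0, 1]}
  - {name: prom,                kind: discrete,   domain: [0, 1]}
  - {name: placenta_previa,     kind: discrete,   domain: [0, 1]}
  - {name: single_umbilical_artery, kind: discrete, domain: [0, 1]}
  - {name: abnormal_cord_insertion, kind: discrete, domain: [0, 1]}
  - {name: dvt,                 kind: discrete,   domain: [0, 1]}
  - {name: birth_weight,        kind: continuous, domain: [300, 6000], units: g}
outcome:
  name: delivery_class
  positive_label: 1   # emergency cesarean section
  negative_label: 2   # vaginal delivery or elective cesarean
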