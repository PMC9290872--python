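# Packaged 15-rule emergency-cesarean rule set (perinatal52 schema).
# Class 1 = emergency cesarean section; class 2 = vaginal delivery or
# elective cesarean. Conditions are conjunctions, applied first-match in
# listed order. Rules 9 and 10 are antecedent-identical with opposite
# consequents exactly as published; the auditor flags the conflict rather
# than resolving it.
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight <= 2118 AND gdm = 0 THEN 1
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight <= 2118 AND gdm = 0 AND birth_weight <= 1152 THEN 1
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight <= 2118 AND gdm = 0 AND birth_weight <= 1152 AND maternal_height <= 159.5 THEN 1
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight <= 2118 AND gdm = 1 AND birth_weight > 1152 AND maternal_height <= 159.5 AND hdp = 0 AND maternal_age <= 29.5 THEN 2
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight <= 2118 AND gdm = 1 AND birth_weight > 1152 AND maternal_height <= 159.5 AND hdp = 0 AND maternal_age > 29.5 THEN 1
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight <= 2118 AND gdm = 1 AND birth_weight > 1152 AND hdp = 0 THEN 1
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight > 2118 AND placenta_previa = 0 AND infertility_treatment = 0 THEN 2
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight > 2118 AND placenta_previa = 0 AND infertility_treatment = 1 AND maternal_age <= 33 AND bmi <= 21.4 THEN 2
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight > 2118 AND placenta_previa = 0 AND infertility_treatment = 1 AND maternal_age <= 33 AND bmi > 21.4 THEN 1
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight > 2118 AND placenta_previa = 0 AND infertility_treatment = 1 AND maternal_age <= 33 AND bmi > 21.4 THEN 2
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity <= 2 AND birth_weight > 2118 AND placenta_previa = 1 THEN 1
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth <= 0.13 AND parity > 2 THEN 2
IF birth_weight <= 2456 AND prior_cs <= 0.32 AND preterm_birth > 0.13 THEN 2
IF birth_weight <= 2456 AND prior_cs > 0.32 THEN 1
IF birth_weight > 2456 THEN 2
DEFAULT 2
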