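{
  "entries": [
    {"canonical": "person_id", "hrs": "PN", "charls": "ID", "recode": "identity"},
    {"canonical": "wave_index", "hrs": "WAVE", "charls": "WAVE", "recode": "identity"},
    {"canonical": "calendar_year", "hrs": "YEAR", "charls": "YEAR", "recode": "identity"},
    {"canonical": "birth_year", "hrs": "RABYEAR", "charls": "RABYEAR", "recode": "identity"},
    {"canonical": "gender", "hrs": "RAGENDER", "charls": "RAGENDER", "recode": "gender_code"},
    {"canonical": "marital_status", "hrs": "R1MSTAT", "charls": "R1MSTAT", "recode": "marital_code"},
    {"canonical": "bmi", "hrs": "R1BMI", "charls": "R1MBMI", "recode": "identity"},
    {"canonical": "education_years", "hrs": "RAEDYRS", "charls": "RAEDUC_C", "recode_hrs": "identity", "recode_charls": "education_category"},
    {"canonical": "smoke_ever", "hrs": "R1SMOKEV", "charls": "R1SMOKEV", "recode": "int_bool"},
    {"canonical": "smoke_now", "hrs": "R2SMOKEN", "charls": "R2SMOKEN", "recode": "int_bool"},
    {"canonical": "smoking_frequency", "hrs": "R1SMOKEF", "charls": "R1SMOKEF", "recode": "identity"},
    {"canonical": "cessation_duration", "hrs": "R1CESSDU", "charls": "R1CESSDU", "recode": "identity"},
    {"canonical": "vigorous_activity", "hrs": "R1VGACTF", "charls": "R1VGACT_C", "recode": "int_bool"},
    {"canonical": "drinking", "hrs": "R1DRINK", "charls": "R1DRINK", "recode": "int_bool"},
    {"canonical": "prevention_behavior", "hrs": "R1CHOLST", "charls": null, "recode": "int_bool"},
    {"canonical": "cancer_history", "hrs": "R1CANCRE", "charls": "R1CANCRE", "recode": "int_bool"},
    {"canonical": "lung_disease", "hrs": "R1LUNGE", "charls": "R1LUNGE", "recode": "int_bool"},
    {"canonical": "lung_cancer_event", "hrs": "LUNGCA", "charls": "LUNGCA", "recode": "int_bool"},
    {"canonical": "death_event", "hrs": "DEATH", "charls": "DEATH", "recode": "int_bool"}
  ]
}
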