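# Editable ICD-10 code sets for the comorbidity report.
# Format: name = PREFIX or RANGE, semicolon-separated.
# Labels without a canonical ICD block are explicit assumptions.
depression = F32; F33
organic_mental_disorders = F06
somatoform_disorders = F45
personality_behavioral_disorders = F07
vascular_disorders = I60–I79; G45
gastrointestinal_disorders = K20–K93
hypertension = I10–I15
head_injury = S00–S09
trunk_limb_injury = T08–T14
knee_lower_leg_injury = S80–S89
ankle_foot_injury = S90–S99
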