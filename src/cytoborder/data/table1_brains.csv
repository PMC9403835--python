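brain,sex,age_years,cause_of_death,fresh_brain_weight_g
BC04,M,75,Acute glomerulonephritis,1349
BC05,F,59,Cardiorespiratory insufficiency,1142
BC08,F,72,Renal failure,1216
BC09,F,79,Cardiorespiratory insufficiency,1110
BC10,F,85,Mesenteric infarction,1046
BC11,M,74,Myocardial infarction,1381
BC13,M,39,Drowning,1234
BC14,F,86,Cardiorespiratory insufficiency,1113
BC20,M,65,Cardiorespiratory insufficiency,1392
BC21,M,30,Bronchopneumonia,1409
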