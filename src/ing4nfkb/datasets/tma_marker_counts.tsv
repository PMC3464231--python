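subgroup	n	ing4_low	ing4_high
total	227	77	150
ER+	156	55	101
ER-	63	18	45
HER2-	197	67	130
HER2+	27	9	18
pp65_low	166	48	118
pp65_high	62	29	33
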