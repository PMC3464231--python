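ing4	pp65	ln_neg	ln_pos	printed_neg_pct	printed_pos_pct
low	low	17	11	61	39
low	high	6	8	43	57
high	low	35	15	70	30
high	high	8	3	73	27
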