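feature	subcategory	ing4_low	ing4_high	printed_low_pct	printed_high_pct
subtype	DCIS	0	6	0	100
subtype	IDC	51	108	32	68
subtype	ILC	6	14	30	70
size	lt2cm	8	21	28	72
size	ge2cm	47	68	41	59
grade	grade1	8	20	27	71
grade	grade2	29	43	40	60
grade	grade3	17	25	41	59
ln_status	N0	23	43	35	65
ln_status	gtN0	19	18	51	49
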