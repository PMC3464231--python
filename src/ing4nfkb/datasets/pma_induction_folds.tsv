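gene	fold_control	fold_ing4
IL6	26	8
IL8	1070	35
PTGS2	212	10
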