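state	residue
cis	459
cis	469
cis	2859
trans	818
trans	1005
trans	1057
trans	1703
trans	1994
trans	2200
trans	2413
trans	2859
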