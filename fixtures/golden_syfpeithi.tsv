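allele	peptide	score
HLA-A*02:01	WLMPVIPAL	21
HLA-A*02:01	WLTPVIPAL	17
HLA-A*02:01	FLACHLFVI	19
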