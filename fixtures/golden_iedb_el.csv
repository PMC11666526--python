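allele,peptide,score
HLA-A*02:01,WLMPVIPAL,0.92
HLA-A*02:01,WLTPVIPAL,0.44
HLA-A*02:01,FLACHLFVI,0.81
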