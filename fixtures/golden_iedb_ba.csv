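allele,peptide,ic50
HLA-A*02:01,WLMPVIPAL,41.7
HLA-A*02:01,WLTPVIPAL,230.1
HLA-A*02:01,FLACHLFVI,88.9
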