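HLA-A*02:01
Pos	Peptide	ID	1-log50k	nM	Rank
1	WLMPVIPAL	NANOGNB	0.674	34.2	0.12
2	WLTPVIPAL	NANOGNB	0.512	198.5	0.90
3	FLACHLFVI	TAS2R46	0.601	76.0	0.35
4	FLVCHLFVI	TAS2R46	0.488	260.3	1.20
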