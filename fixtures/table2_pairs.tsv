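pair_id	gene	wt_seq	mt_seq	mutation_type	foci
LUAD-1	TAS2R46	FLVCHLFVI	FLACHLFVI	SNV	P4.1;P4.2;P4.3;P4.4
LUAD-2	ATP2B3	TKSATSSVF	HQVSYLFSV	INDEL	P4.3
LUAD-3	KCNE4	GIFLIGIML	FLDRNHAGL	INDEL	P4.2
LUAD-4	TSPAN7	FLEHGIPPS	FLEHGIPPA	SNV	P4.4
LUAD-5	USP40	YLQGAPYYL	YLQGALYYL	SNV	P4.4
LUAD-6	UBQLN2	GPTVSSAAPS	GLLCPALHLV	INDEL	P4.1;P4.4
LUAD-7	NANOGNB	WLTPVIPAL	WLMPVIPAL	SNV	P4.1;P4.3;P4.4
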