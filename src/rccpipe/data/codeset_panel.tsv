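name	probe_class	category	accession	target_start	target_end	concentration_fM
IFNG	endogenous	Pro-inflammatory cytokine	NM_174086.1	503	602	0
IL1B	endogenous	Pro-inflammatory cytokine	NM_174093.1	331	430	0
IL6	endogenous	Pro-inflammatory cytokine	NM_173923.2	293	392	0
IL8	endogenous	Pro-inflammatory cytokine	NM_173925.2	278	377	0
TNFA	endogenous	Pro-inflammatory cytokine	NM_173966.2	950	1049	0
IL10	endogenous	Anti-inflammatory cytokine	NM_174088.1	145	244	0
AGTR2	endogenous	Neuroactive ligand-receptor	XM_001249373.2	1206	1305	0
CRH	endogenous	Neuroactive ligand-receptor	NM_001013400.1	443	542	0
NGF	endogenous	Neuroactive ligand-receptor	NM_001099362.1	558	657	0
NOS1	endogenous	Neuroactive ligand-receptor	XM_867630.5	2657	2756	0
PGHS2	endogenous	Neuroactive ligand-receptor	NM_174445.2	881	980	0
TAC1	endogenous	Neuroactive ligand-receptor	NM_174193.1	317	416	0
GAPDH	reference	Reference	NM_001034034.1	213	312	0
GUSB	reference	Reference	NM_001083436.1	1815	1914	0
YWHAZ	reference	Reference	NM_174814.2	147	246	0
POS_A	positive	Positive	POS_A(128)			128
POS_B	positive	Positive	POS_B(32)			32
POS_C	positive	Positive	POS_C(8)			8
POS_D	positive	Positive	POS_D(2)			2
POS_E	positive	Positive	POS_E(0.5)			0.5
POS_F	positive	Positive	POS_F(0.125)			0.125
NEG_A	negative	Negative	NEG_A(0)			0
NEG_B	negative	Negative	NEG_B(0)			0
NEG_C	negative	Negative	NEG_C(0)			0
NEG_D	negative	Negative	NEG_D(0)			0
NEG_E	negative	Negative	NEG_E(0)			0
NEG_F	negative	Negative	NEG_F(0)			0
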