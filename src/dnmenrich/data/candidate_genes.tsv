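# 58 prioritized candidate genes: LGD hit counts and effect types observed in
# 3953 ASD families, RNA-binding-protein target membership (F = FMRP target,
# R = RBFOX target, Both = both), RVIS percentile and pLI score.  '-' = missing.
gene	lgd_count	effect_types	fmrp_rbfox	rvis_pct	pli
ATP1A1	1	SP	Both	5.00	1.00
CUX2	1	SG	F	9.20	1.00
DSCAML1	1	SP	F	0.67	1.00
ELAVL2	1	FS	R	15.85	0.96
FAM91A1	1	SG	F	21.65	0.88
FBXW11	1	SG	R	20.08	1.00
RAPGEF4	1	SP	Both	9.59	1.00
SMARCE1	1	SP	R	23.48	1.00
SPTBN1	1	SG	F	0.17	1.00
TANC2	1	SG	Both	0.37	1.00
UBAP2L	1	FS	F	3.33	1.00
UBR3	1	FS	Both	-	1.00
UBR5	1	FS	Both	0.21	1.00
ZNF462	1	FS	F	1.09	1.00
BRSK2	1	SP	Both	4.95	0.89
DST	1	FS	Both	0.28	1.00
EP400	1	FS	Both	7.32	1.00
GRIN2B	3	FS,SG,SP	Both	1.28	1.00
NBEA	1	SG	Both	1.16	1.00
NCKAP1	2	FS,SG	Both	3.85	1.00
NRXN1	1	SG	Both	1.78	1.00
SKI	1	SG	Both	11.79	0.97
SPAG9	1	FS	Both	14.41	1.00
TRIM37	1	SP	Both	5.31	1.00
BAI1	1	SG	F	-	1.00
BIRC6	1	SG	F	0.07	1.00
CIC	1	SG	F	0.83	1.00
DIP2A	2	SG,FS	F	8.68	1.00
DIP2C	1	FS	F	0.61	1.00
DOT1L	1	SG	F	2.18	1.00
KDM4B	1	SG	F	13.00	1.00
KIAA0100	1	SG	F	2.12	0.92
KIAA2018	1	SG	F	-	1.00
NF1	1	SG	F	0.39	1.00
RALGAPB	1	FS	F	3.00	1.00
RELN	1	SG	F	5.17	1.00
SHANK2	1	FS	F	2.03	1.00
SMARCC2	1	SP	F	8.51	1.00
STXBP5	1	FS	F	4.70	1.00
TRIO	1	FS	F	0.57	1.00
BAZ2B	1	FS	R	13.09	1.00
BRWD1	1	FS	R	10.52	1.00
CSDE1	1	SG	R	6.18	1.00
CUL1	1	SP	R	9.85	1.00
ERBB2IP	1	SP	R	-	1.00
GABRB3	1	FS	R	25.36	1.00
GGNBP2	1	SG	R	27.26	1.00
GRIA2	1	SG	R	10.77	1.00
HECTD1	1	FS	R	0.45	1.00
MPP6	1	SP	R	26.90	0.99
NFIA	1	SG	R	18.59	1.00
NFIB	1	SP	R	16.62	0.98
PCSK2	1	FS	R	19.29	1.00
PRPF40A	1	SP	R	8.28	0.88
RANBP2	1	FS	R	1.77	1.00
UNC79	1	FS	R	1.27	1.00
XKR6	1	SG	R	16.93	1.00
YTHDC1	1	FS	R	18.25	1.00
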