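individual_id	role	cohort	gene	effect	inheritance	nt_change	aa_change	ref_pop_maf	low_confidence
HU1.p1	proband	BCM	TANC2	splice_site	de_novo	c.1219+1G>A		0.0	false
CC1.p1	proband	ACGC	TANC2	splice_site	de_novo	c.1219+1G>A		0.0	false
MA.p1	proband	Melbourne	TANC2	frameshift	de_novo	c.1586_1587delAG	p.R530Kfs*5	0.0	false
SS1.p1	proband	SSC	TANC2	stopgain	de_novo	c.3196C>T	p.R1066*	0.0	false
TC.p1	proband	Toronto	TANC2	frameshift	de_novo	c.3828delA	p.E1277Kfs*7	0.0	false
HU2.p1	proband	BCM	TANC2	splice_site	de_novo	c.4016+2T>G		0.0	false
AN.p1	proband	Amsterdam	TANC2	stopgain	de_novo	c.4198C>T	p.Q1400*	0.0	false
LG.p1	proband	Leipzig	TANC2	frameshift	de_novo	c.4405delC	p.R1469Gfs*6	0.0	false
NN1.p1	proband	Nijmegen	TANC2	stopgain	de_novo	c.4447C>T	p.Q1483*	0.0	false
LN.p1	proband	Leiden	TANC2	frameshift	de_novo	c.4449delG	p.Q1483Hfs*69	0.0	false
PF.p1	proband	Paris	TANC2	frameshift	de_novo	c.5319_5344dup	p.F1782Cfs*6	0.0	false
SS2.p1	proband	SSC	TANC2	splice_site	paternal	c.547+1G>A		0.0	false
NN2.p1	proband	Nijmegen	TANC2	frameshift	maternal	c.2781delA	p.A928Qfs*4	0.0	false
TI.p1	proband	Troina	TANC2	frameshift	paternal	c.2348_2349insCT	p.C784Sfs*22	0.0	false
GU.p1	proband	Greenwood	TANC2	splice_site	maternal	c.3543+1G>T		0.0	false
NN3.p1	proband	Nijmegen	TANC2	frameshift	undetermined	c.4713_4716delTCAG	p.Q1572Ffs*41	0.0	false
CC2.p1	proband	ACGC	TANC2	missense	de_novo	c.2264G>A	p.R755H	4.4e-05	false
NN4.p1	proband	NijmegenID	TANC2	missense	de_novo	c.2278C>T	p.R760C	0.0	false
FS.p1	proband	SCZ	TANC2	missense	de_novo	c.2381C>T	p.A794V	0.0	false
TU.p1	proband	TASC	TANC2	missense	de_novo	c.2882G>A	p.R961Q	4.4e-05	false
SS3.p1	proband	SSC	TANC2	missense	de_novo	c.5066A>G	p.H1689R	0.0	false
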