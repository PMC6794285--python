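# Cohorts that screened for disruptive variants in the worked example, with the
# number of tested probands where the referring center stated one.
cohort	size
BCM	8910
ACGC	2154
Melbourne	209
SSC	2508
Toronto	104
Amsterdam	277
Leipzig	100
Nijmegen
Leiden	1200
Paris	651
Troina	1201
Greenwood	253
NijmegenID	100
SCZ	623
TASC	1045
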