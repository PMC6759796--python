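node1	relation	node2	score
VEGFA	pp	KDR	0.999
VEGFA	pp	FLT1	0.999
VEGFA	pp	NRP2	0.998
JAK2	pp	STAT3	0.998
EGFR	pp	STAT3	0.998
CYP1A1	pp	AHR	0.997
JAK1	pp	STAT3	0.997
ATP1A1	pp	ATP1B1	0.997
IL6	pp	STAT3	0.997
VEGFA	pp	HIF1A	0.996
VEGFA	pp	STAT3	0.994
NRP2	pp	FLT1	0.988
FLT1	pp	KDR	0.988
HIF1A	pp	STAT3	0.986
STAT4	pp	JAK2	0.984
NRP2	pp	KDR	0.983
STAT4	pp	JAK1	0.983
VEGFA	pp	EGFR	0.979
IL6	pp	JAK2	0.975
HIF1A	pp	EGFR	0.973
IL6	pp	JAK1	0.968
JAK1	pp	EGFR	0.966
VEGFA	pp	IL6	0.959
JAK2	pp	JAK1	0.943
STAT4	pp	STAT3	0.938
JAK2	pp	EGFR	0.928
CYP1A1	pp	CYP2B6	0.928
IL6	pp	EGFR	0.921
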