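gene	probe_1	probe_2	max_1	max_2	r2
HLA-DRA	ILMN_1689655	ILMN_2157441	15.03	14.61	0.925
TAP1	ILMN_1751079		14.78		0.759
COL1A1	ILMN_1701308		14.75		0.948
CD14	ILMN_1740015	ILMN_2396444	13.20	14.80	0.732
ELANE	ILMN_1706635		13.87		0.783
CD34	ILMN_1732799	ILMN_2341229	13.59	13.54	0.944
CD19	ILMN_1782704		13.49		0.985
PRTN3	ILMN_1753584		13.16		0.867
CD33	ILMN_1747622		11.66		0.834
KRT8	ILMN_1753584		11.55		0.974
P2RX5	ILMN_1677793		11.09		0.679
MOB3A	ILMN_1721344		10.88		0.326
POLE	ILMN_1728199		10.76		0.409
C19orf48	ILMN_1759184	ILMN_2383484	11.34	10.11	0.266
HMHA1	ILMN_1811392		10.11		0.779
CLYBL	ILMN_1663538		9.30		0.487
ROR1	ILMN_1655904		9.20		0.938
COIL	ILMN_1688034		8.65		-0.001
MS4A1	ILMN_1776939		8.62		0.320
PFAS	ILMN_1755862		8.61		0.216
PTPRC	ILMN_2340217	ILMN_1653652	8.07	8.78	0.347
APOBEC3B	ILMN_2219466		8.23		0.652
TTK	ILMN_1788166		8.09		0.545
WT1	ILMN_1802174		8.00		0.856
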