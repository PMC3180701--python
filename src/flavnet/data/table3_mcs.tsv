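# Published 22x12 minimal-cut-set membership matrix for the two
# pigment-forming objective reactions (PELUDP-RXN, RXN1F-775), with cut-set
# size, unaffected-mode count and gene annotations as printed.
mcs	N-3-D-RXN	LEUCPEL-RXN	D-4-R-RXN	RXN-525	APIGNAR-RXN	RXN-600	RXN-602	RXN-7652	PELUDP-RXN	RXN1F-775	RXN-7775	N-C-S-RXN	total	unaffected	genes
1	0	0	0	0	1	0	0	0	0	0	0	0	1	3	CHI
2	0	0	0	0	0	0	0	0	0	0	0	1	1	3	CHS
3	1	0	0	0	0	1	0	0	0	0	0	0	2	57	F3H, DFR(cy)
4	1	0	0	0	0	0	0	1	0	0	0	0	2	9	F3H, F3'H(i)
5	0	1	0	0	0	1	0	0	0	0	0	0	2	126	ANS(pg), DFR(cy)
6	0	0	1	0	0	1	0	0	0	0	0	0	2	123	DFR(pg), DFR(cy)
7	1	0	0	0	0	0	1	0	0	0	0	0	2	60	F3H, ANS(cy)
8	0	1	0	0	0	0	1	0	0	0	0	0	2	132	ANS(pg), ANS(cy)
9	0	0	1	0	0	0	1	0	0	0	0	0	2	129	DFR(pg), ANS(cy)
10	0	0	0	0	0	1	0	0	1	0	0	0	2	129	DFR(cy), 3-UGT(pg)
11	0	0	0	0	0	0	1	0	1	0	0	0	2	135	ANS(cy), 3-UGT(pg)
12	1	0	0	0	0	0	0	0	0	1	0	0	2	63	F3H, 3-UGT(cy)
13	0	1	0	0	0	0	0	0	0	1	0	0	2	138	ANS(pg), 3-UGT(cy)
14	0	0	1	0	0	0	0	0	0	1	0	0	2	135	DFR(pg), 3-UGT(cy)
15	0	0	0	0	0	0	0	0	1	1	0	0	2	141	3-UGT(pg), 3-UGT(cy)
16	1	0	0	0	0	0	0	0	0	0	1	0	2	18	F3H, F3H(cy)
17	0	1	0	1	0	0	0	1	0	0	0	0	3	39	ANS, F3'H, F3'H
18	0	0	1	1	0	0	0	1	0	0	0	0	3	36	DFR, F3'H, F3'H
19	0	0	0	1	0	0	0	1	1	0	0	0	3	42	F3'H, F3'H, 3-UGT(pg)
20	0	1	0	1	0	0	0	0	0	0	1	0	3	48	ANS, F3'H, F3H(cy)
21	0	0	1	1	0	0	0	0	0	0	1	0	3	45	DFR, F3'H, F3H(cy)
22	0	0	0	1	0	0	0	0	1	0	1	0	3	51	F3'H(ii), 3-UGT(pg), F3H(cy)
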