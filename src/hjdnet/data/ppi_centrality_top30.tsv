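metric	rank	node	value
degree	1	TP53	66
degree	2	AKT1	49
degree	3	EGF	47
degree	4	PCNA	47
degree	5	JUN	46
degree	6	VEGFA	44
degree	7	ESR1	42
degree	8	IL6	42
degree	9	CDK1	41
degree	10	BCL2	41
degree	11	HSP90AA1	40
degree	12	CDK2	40
degree	13	CCND1	40
degree	14	EGFR	40
degree	15	TNF	39
degree	16	CDKN1A	38
degree	17	PIK3CG	37
degree	18	FOS	37
degree	19	HSPA4	37
degree	20	MAPK8	35
degree	21	AR	34
degree	22	CCNB1	33
degree	23	NOS3	33
degree	24	PTGS2	33
degree	25	CHEK1	30
degree	26	CDKN1B	30
degree	27	MMP2	30
degree	28	MAPK14	30
degree	29	CCNA2	29
degree	30	MDM2	29
betweenness	1	TP53	0.12965202
betweenness	2	HSP90AA1	0.07551998
betweenness	3	HSPA4	0.06902023
betweenness	4	IL6	0.06776382
betweenness	5	AKT1	0.04867524
betweenness	6	VEGFA	0.04389668
betweenness	7	PCNA	0.03662677
betweenness	8	EGF	0.034913
betweenness	9	ESR1	0.02917485
betweenness	10	JUN	0.02822688
betweenness	11	TNF	0.02701286
betweenness	12	CDK1	0.02175952
betweenness	13	PTGS2	0.02156667
betweenness	14	PPARG	0.02083383
betweenness	15	AKR1C3	0.02075601
betweenness	16	ALOX5	0.02061856
betweenness	17	AR	0.01863776
betweenness	18	CDK2	0.01810019
betweenness	19	NOS3	0.017597
betweenness	20	EGFR	0.01749873
betweenness	21	CCND1	0.01665403
betweenness	22	MAPK8	0.01587777
betweenness	23	CDKN1A	0.01556023
betweenness	24	BCL2	0.0151564
betweenness	25	FOS	0.01323593
betweenness	26	MMP2	0.0125
betweenness	27	PGR	0.00972
betweenness	28	CDKN1B	0.00965
betweenness	29	PIK3CG	0.00952
betweenness	30	CALM2	0.00918
closeness	1	TP53	0.75193798
closeness	2	AKT1	0.65986395
closeness	3	EGF	0.65100671
closeness	4	VEGFA	0.64666667
closeness	5	PCNA	0.64666667
closeness	6	JUN	0.64666667
closeness	7	IL6	0.63815789
closeness	8	ESR1	0.62987013
closeness	9	BCL2	0.62580645
closeness	10	EGFR	0.62179487
closeness	11	HSP90AA1	0.61783439
closeness	12	TNF	0.61783439
closeness	13	CDKN1A	0.61006289
closeness	14	FOS	0.61006289
closeness	15	PIK3CG	0.61006289
closeness	16	HSPA4	0.60625
closeness	17	CDK2	0.60625
closeness	18	AR	0.60248447
closeness	19	MAPK8	0.60248447
closeness	20	PTGS2	0.59876543
closeness	21	CDK1	0.59509202
closeness	22	CCND1	0.59509202
closeness	23	NOS3	0.59146341
closeness	24	MMP2	0.58083832
closeness	25	MAPK14	0.58083832
closeness	26	CALM2	0.57058824
closeness	27	CALM1	0.57058824
closeness	28	CDKN1B	0.56725146
closeness	29	MDM2	0.56725146
closeness	30	KDR	0.55747126
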