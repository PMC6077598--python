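pathway	C	O	E	R	rawP	adjP	genes
Cell cycle	124	24	1.59	15.09	0.0	0.0	CDK2;CDK7;CDKN1A;CDKN1B;CHEK1;MCM5;MDM2;PCNA;ATY;CCND1;BUB1B;TP53;CCNA2;CCNA1;CCNB1;CCND3;CCNE1;CCNH;CCNB2;CCNE2;CDK1;CDC6;CDC20;CDC25C
Pathways in cancer	397	31	5.09	6.09	0.0	0.0	CDK2;CDKN1A;CDKN1B;CKS1B;CKS2;EGF;EGFR;AKT1;FOS;GSTP1;HSP90AA1;IL6;AR;JUN;MDM2;MMP1;MMP2;PIK3CG;PPARG;MAPK8;PTGS2;CCND1;BCL2;RXRA;RXRB;TP53;VEGFA;VEGFC;CCNA1;CCNE1;CCNE2
p53 signaling pathway	69	15	0.88	16.95	4.22e-15	3.78e-13	CDK2;CDKN1A;CHEK1;MDM2;MDM4;SERPINE1;ATR;CCND1;TP53;CCNB1;CCND3;CCNE1;CCNB2;CCNE2;CDK1
AGE-RAGE signaling pathway in diabetic complications	101	17	1.3	13.13	5e-15	3.78e-13	CDKN1B;COL1A1;MAPK14;AKT1;F3;IL6;JUN;MMP2;NOS3;SERPINE1;PIK3CG;MAPK8;CCND1;BCL2;TNF;VEGFA;VEGFC
Prostate cancer	89	16	1.14	14.02	1.15e-14	7e-13	CDK2;CDKN1A;CDKN1B;EGF;EGFR;AKT1;GSTP1;HSP90AA1;AR;MDM2;PIK3CG;CCND1;BCL2;TP53;CCNE1;CCNE2
Endocrine resistance	98	16	1.26	12.73	5.64e-14	2.85e-12	CDKN1A;CDKN1B;MAPK14;EGFR;AKT1;ESR1;ESR2;FOS;JUN;MDM2;MMP2;PIK3CG;MAPK8;CCND1;BCL2;TP53
Hepatitis B	146	18	1.87	9.62	2.03e-13	8.77e-12	CDK2;CDKN1A;CDKN1B;AKT1;FOS;IL6;JUN;PCNA;PIK3CG;MAPK8;CCND1;BCL2;TNF;TP53;CCNA2;CCNA1;CCNE1;CCNE2
PI3K-Akt signaling pathway	341	25	4.37	5.72	4.23e-13	1.6e-11	BCL2L11;CDK2;CDKN1A;CDKN1B;CDC37;COL1A1;EGF;EGFR;AKT1;FLT1;HSP90AA1;IL6;KDR;MDM2;NOS3;PIK3CG;CCND1;BCL2;RXRA;TP53;VEGFA;VEGFC;CCND3;CCNE1;CCNE2
Small cell lung cancer	86	14	1.1	12.7	2.52e-12	8.48e-11	CDK2;CDKN1B;CKS1B;CKS2;AKT1;PIK3CG;PTGS2;CCND1;BCL2;RXRA;RXRB;TP53;CCNE1;CCNE2
FoxO signaling pathway	134	15	1.72	8.73	1.03e-10	3.12e-09	BCL2L11;CDK2;CDKN1A;CDKN1B;MAPK14;EGF;EGFR;AKT1;IL6;MDM2;PIK3CG;MAPK8;CCND1;CCNB1;CCNB2
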