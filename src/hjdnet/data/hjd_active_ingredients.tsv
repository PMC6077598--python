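herb	name	ob	dl
Huanglian	(R)-Canadine	55.37	0.77
Huanglian	berberine	36.86	0.78
Huanglian	berberrubine	35.74	0.73
Huanglian	Berlambine	36.68	0.82
Huanglian	coptisine	30.67	0.86
Huanglian	epiberberine	43.09	0.78
Huanglian	palmatine	64.6	0.65
Huanglian	quercetin	46.43	0.28
Huanglian	Worenine	45.83	0.87
Huangqin	(2R)-7-hydroxy-5-methoxy-2-phenylchroman-4-one	55.23	0.2
Huangqin	5,2′,6′-Trihydroxy-7,8-dimethoxyflavone	45.05	0.33
Huangqin	5,2′-Dihydroxy-6,7,8-trimethoxyflavone	31.71	0.35
Huangqin	5,7,2,5-tetrahydroxy-8,6-dimethoxyflavone	33.82	0.45
Huangqin	5,7,2′,6′-Tetrahydroxyflavone	37.01	0.24
Huangqin	5,7,4′-trihydroxy-6-methoxyflavanone	36.63	0.27
Huangqin	5,7,4′-trihydroxy-8-methoxyflavanone	74.24	0.26
Huangqin	5,7,4′-Trihydroxy-8-methoxyflavone	36.56	0.27
Huangqin	acacetin	34.97	0.24
Huangqin	baicalein	33.52	0.21
Huangqin	beta-sitosterol	36.91	0.75
Huangqin	Carthamidin	41.15	0.24
Huangqin	Dihydrobaicalin_qt	40.04	0.21
Huangqin	Dihydrooroxylin	66.06	0.23
Huangqin	ent-Epicatechin	48.96	0.24
Huangqin	Eriodyctiol (flavanone)	41.35	0.24
Huangqin	Moslosooflavone	44.09	0.25
Huangqin	NEOBAICALEIN	104.34	0.44
Huangqin	Norwogonin	39.4	0.21
Huangqin	oroxylin a	41.37	0.23
Huangqin	Panicolin	76.26	0.29
Huangqin	rivularin	37.94	0.37
Huangqin	Salvigenin	49.07	0.33
Huangqin	sitosterol	36.91	0.75
Huangqin	Skullcapflavone II	69.51	0.44
Huangqin	Stigmasterol	43.83	0.76
Huangqin	wogonin	30.68	0.23
Huangbo	(S)-Canadine	53.83	0.77
Huangbo	campesterol	37.58	0.71
Huangbo	Cavidine	35.64	0.81
Huangbo	Chelerythrine	34.18	0.78
Huangbo	Dehydrotanshinone II A	43.76	0.4
Huangbo	delta 7-stigmastenol	37.42	0.75
Huangbo	Fumarine	59.26	0.83
Huangbo	Hericenone H	39	0.63
Huangbo	Isocorypalmine	35.77	0.59
Huangbo	phellamurin_qt	56.6	0.39
Huangbo	Phellavin_qt	35.86	0.44
Huangbo	Phellopterin	40.19	0.28
Huangbo	poriferast-5-en-3beta-ol	36.91	0.75
Huangbo	rutaecarpine	40.3	0.6
Huangbo	Skimmianin	40.14	0.2
Huangbo	thalifendine	44.41	0.73
Zhizi	3-Methylkempferol	32.03	0.76
Zhizi	5-hydroxy-7-methoxy-2-(3,4,5-trimethoxyphenyl) chromone	34.55	0.22
Zhizi	Ammidin	84.07	0.59
Zhizi	crocetin	36.91	0.75
Zhizi	isoimperatorin	42	0.19
Zhizi	kaempferol	33.55	0.42
Zhizi	Mandenol	45.46	0.23
Zhizi	Sudan III	60.16	0.26
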