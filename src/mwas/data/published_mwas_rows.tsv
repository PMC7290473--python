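Analysis	Plan	ProbeID	Chr	ProbePos	Gene	SNP	Pos	A1	Freq	P_GWAS	P_mQTL	b_SMR	SE_SMR	P_SMR	P_HEIDI	N_HEIDI	Current	Previous	Region
blood	males	cg05206559	19q13.32	45913997	NANOS2	rs66529687	45914171	A	0.133	1.83E-04	2.84E-41	0.723	0.125	7.67E-09	3.28E-01	20	G	G	G
blood	males	cg25673584	19q13.32	45914293	NANOS2	rs66529687	45914171	A	0.133	1.83E-04	4.40E-30	0.849	0.152	2.45E-08	1.23E-01	20	G	G	G
blood	males	cg14192299	19q13.32	45914381	NANOS2	rs66529687	45914171	A	0.133	1.83E-04	6.71E-42	0.718	0.124	7.30E-09	1.08E-01	20	G	G	G
blood	males	cg19702802	19q13.32	45914471	NANOS2	rs66529687	45914171	A	0.133	1.83E-04	3.22E-39	0.743	0.129	9.10E-09	1.03E-01	20	G	G	G
blood	females	cg10218546	6p21.32	32762046	HLA-DQB2	rs7768538	32762044	C	0.426	6.15E-05	1.30E-126	-0.304	0.060	3.27E-07	6.43E-02	20	S	G	G
blood	htn	cg23395749	5q35.3	177557245	FAM193B	rs1001530	177558514	G	0.046	3.36E-04	2.55E-26	-0.484	0.088	3.08E-08	8.77E-02	5	N	S	S
blood	no_htn	cg08631357	5q32	150209647	SLC6A7	rs10076748	150209303	A	0.107	1.77E-03	1.54E-193	0.288	0.056	3.18E-07	2.02E-01	20	N	N	G
blood	no_htn	cg23891049	7q33	134679117	BPGM	rs73441994	134679118	A	0.021	4.26E-02	1.18E-229	-0.156	0.030	1.70E-07	6.07E-01	4	N	S	S
blood	no_htn	cg24635736	10q26.13	122979534	PSTK	rs2421140	123027854	A	0.029	8.09E-03	2.67E-77	-0.346	0.060	6.12E-09	7.16E-01	8	N	N	N
blood	no_htn	cg05360847	11q13.4	71576873	KRTAP5-11	rs11827208	71578103	T	0.020	1.70E-03	3.47E-13	-0.942	0.159	3.50E-09	2.02E-01	4	N	N	S
blood	no_htn	cg17632299	13q14.3	52738831	LECT1	rs4885947	52735009	C	0.037	1.23E-03	7.51E-54	0.592	0.085	2.67E-12	1.34E-01	20	N	G	G
blood	no_htn	cg09557313	13q14.3	52739039	LECT1	rs4885947	52735009	C	0.037	1.23E-03	1.46E-40	0.675	0.100	1.37E-11	1.02E-01	20	N	G	G
blood	no_htn	cg09397293	16p13.3	2005032	ZNF598	rs72766639	2005819	A	0.174	1.69E-04	5.78E-51	0.688	0.116	3.06E-09	2.85E-01	20	N	S	G
blood	no_htn	cg26804891	16p13.3	2005241	ZNF598	rs11248905	1999727	T	0.181	4.88E-05	3.56E-98	0.539	0.080	1.62E-11	7.60E-02	20	N	S	G
blood	no_htn	cg08576185	16p13.3	2005683	ZNF598	rs72766639	2005819	A	0.174	1.69E-04	4.06E-44	0.740	0.126	4.76E-09	3.59E-01	20	N	S	G
blood	no_htn	cg10470208	16p13.3	2008700	ZNF598	rs1058474	1998795	T	0.181	6.82E-05	6.56E-19	1.112	0.209	1.02E-07	7.58E-02	14	N	S	G
blood	no_htn	cg06998361	16q21	58110599	C16orf80	rs10445026	58109349	G	0.069	5.00E-04	5.61E-97	-0.442	0.069	1.35E-10	2.53E-01	20	N	S	S
blood	no_htn	cg03063511	2p13.1	73930386	DGUOK	rs6737156	73932607	C	0.036	5.62E-03	2.71E-227	-0.247	0.041	2.74E-09	1.09E-01	11	N	N	N
blood	no_htn	cg02850715	11q24.3	130159317	ST14	rs34008994	130165703	T	0.096	1.55E-04	1.21E-26	-0.812	0.138	4.14E-09	7.87E-01	20	N	N	G
blood	no_htn	cg21029769	11q24.3	130159620	ST14	rs34008994	130165703	T	0.096	1.55E-04	4.09E-18	-1.006	0.184	4.58E-08	9.16E-01	20	N	N	G
brain	males	cg05206559	19q13.32	45913997	NANOS2	rs66529687	45914171	G	0.867	1.83E-04	5.86E-298	0.272	0.043	2.96E-10	8.50E-01	19	G	G	G
brain	females	cg04322111	6p21.32	32761987	HLA-DQB2	rs7768538	32762044	A	0.574	6.15E-05	1.00E-300	-0.201	0.039	2.21E-07	8.61E-02	20	S	G	G
brain	females	cg10218546	6p21.32	32762046	HLA-DQB2	rs7768538	32762044	A	0.574	6.15E-05	1.00E-300	-0.198	0.038	2.18E-07	8.32E-02	20	S	G	G
brain	htn	cg23395749	5q35.3	177557245	FAM193B	rs1001530	177558514	A	0.954	3.36E-04	2.34E-15	-0.791	0.157	5.17E-07	1.01E-01	5	N	S	S
brain	no_htn	cg08631357	5q32	150209647	SLC6A7	rs10076748	150209303	C	0.893	1.77E-03	2.82E-295	0.230	0.045	2.76E-07	2.24E-01	18	N	N	G
brain	no_htn	cg10308629	7q33	134670051	BPGM	rs73439998	134663724	C	0.979	3.01E-02	9.28E-48	-0.520	0.101	2.88E-07	2.57E-01	3	N	S	S
brain	no_htn	cg24635736	10q26.13	122979534	PSTK	rs13328826	122992107	A	0.970	6.26E-03	2.48E-20	-0.374	0.072	1.68E-07	8.24E-01	3	N	N	N
brain	no_htn	cg15567360	11q13.4	71611653	KRTAP5-11	rs11827208	71578103	C	0.980	1.70E-03	9.66E-10	-0.679	0.130	1.67E-07	3.71E-01	3	N	N	S
brain	no_htn	cg09557313	13q14.3	52739039	LECT1	rs4885961	52755200	C	0.960	4.63E-03	6.93E-31	0.547	0.103	1.06E-07	5.67E-01	7	N	G	G
brain	no_htn	cg07011318	16p13.3	2004943	ZNF598	rs72766639	2005819	G	0.826	1.69E-04	1.00E-300	0.291	0.046	1.96E-10	1.12E-01	17	N	S	G
brain	no_htn	cg09397293	16p13.3	2005032	ZNF598	rs72766639	2005819	G	0.826	1.69E-04	1.00E-300	0.282	0.044	1.86E-10	1.13E-01	18	N	S	G
brain	no_htn	cg05211189	16p13.3	2005402	ZNF598	rs11542302	1986934	T	0.819	7.26E-05	1.00E-300	0.283	0.043	7.47E-11	1.01E-01	18	N	S	G
brain	no_htn	cg08576185	16p13.3	2005683	ZNF598	rs72766639	2005819	G	0.826	1.69E-04	1.00E-300	0.295	0.046	2.00E-10	9.02E-02	16	N	S	G
brain	no_htn	cg06998361	16q21	58110599	C16orf80	rs74019790	58107923	T	0.931	5.00E-04	4.77E-20	-0.591	0.109	5.49E-08	6.81E-01	11	N	S	S
brain	no_htn	cg11003133	1q23.1	159076601	AIM2	rs16841642	159077008	G	0.952	5.30E-03	6.30E-82	-0.312	0.062	4.62E-07	3.40E-01	18	N	S	N
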