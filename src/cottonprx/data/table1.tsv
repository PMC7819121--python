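gene_name	gene_id	subclade	exon_count	protein_aa	pI	mw_da	chromosome	start	end	notes
GhPRX1-A	Gh_A01G1793	PRX2	1	228	9.1	24095.74	ChrA01	97705624	97706307
GhPRX2-A	Gh_A04G0493	PRX1	7	266	6.19	29149.42	ChrA04	26311787	26315757
GhPRX3-A	Gh_A05G3849	TPX	3	163	5.6	17466.1	ChrA05	104118	105049	text places this gene on scaffolds; coordinates follow the printed table
GhPRX4-A	Gh_A08G2151	TPX	3	163	5.58	17226.79	ChrA08	102615361	102616794
GhPRX5-A	Gh_A08G2202	PRXQ	4	217	9.74	23887.43	ChrA08	103031734	103033703
GhPRX6-A	Gh_A10G1104	PRX5	5	199	8.98	21446.44	ChrA10	54462313	54464296
GhPRX7-A	Gh_A10G1567	PRX6	4	220	5.98	24555.88	ChrA10	85538436	85539624
GhPRX8-D	Gh_D01G2034	PRX2	1	228	9.1	24111.83	ChrD01	59334370	59335053
GhPRX9-D	Gh_D04G0917	PRX1	7	266	6.19	29043.3	ChrD04	26446572	26450644
GhPRX10-D	Gh_D05G0244	TPX	3	147	6.82	15755.16	ChrD05	2202510	2204565
GhPRX11-D	Gh_D05G1251	TPX	3	163	5.78	17454.09	ChrD05	10748631	10749537
GhPRX12-D	Gh_D08G2518	TPX	3	163	5.58	17196.76	ChrD08	64930986	64932473
GhPRX13-D	Gh_D08G2567	PRXQ	4	217	9.7	23793.27	ChrD08	65350134	65351542
GhPRX14-D	Gh_D10G1403	PRX5	5	199	8.45	21361.29	ChrD10	28600472	28602454
GhPRX15-D	Gh_D10G1825	PRX6	4	220	6.22	24392.79	ChrD10	51342185	51343360
GbPRX1-A	Gbar_A10G018830.1	PRX6	4	219	5.98	24555.88	ChrA10	93866990	93868166
GbPRX2-A	Gbar_A08G026850.1	PRXQ	4	216	9.74	23887.43	ChrA08	119243921	119246359
GbPRX3-A	Gbar_A08G026350.1	TPX	3	162	5.58	17196.76	ChrA08	118790855	118792723
GbPRX4-A	Gbar_A01G020700.1	PRX2	1	227	9.1	24095.74	ChrA01	113395150	113395833
GbPRX5-A	Gbar_A10G013540.1	PRX5	5	198	8.98	21446.44	ChrA10	62896091	62898528
GbPRX6-A	Gbar_A05G012820.1	TPX	3	162	5.6	17466.1	ChrA05	11767776	11768707
GbPRX7-D	Gbar_D10G014760.1	PRX5	5	198	8.45	21333.23	ChrD10	28146247	28148956
GbPRX8-D	Gbar_D04G010400.1	PRX1	7	265	6.19	29103.4	ChrD04	28395391	28400177
GbPRX9-D	Gbar_D08G027530.1	PRXQ	4	216	9.7	23793.27	ChrD08	65405467	65407385
GbPRX10-D	Gbar_D01G021840.1	PRX2	1	227	9.34	24091.84	ChrD01	60905018	60905701
GbPRX11-D	Gbar_D08G027000.1	TPX	3	162	5.58	17196.76	ChrD08	65009751	65011737
GbPRX13-D	Gbar_D05G002520.1	TPX	3	146	6.82	15755.16	ChrD05	2189964	2198116
GbPRX14-D	Gbar_D10G019020.1	PRX6	4	219	6.22	24392.79	ChrD10	51564063	51565371
GrPRX1	Gorai.009G135600.1	TPX	3	162	5.78	17468.12	Chr9	10193477	10194845
GrPRX2	Gorai.009G397800.1	PRX1	7	265	6.19	29043.3	Chr9	56100514	56105218
GrPRX3	Gorai.009G026300.1	TPX	3	163	5.9	17491.13	Chr9	2005154	2007919
GrPRX4	Gorai.011G158200.1	PRX5	10	198	7.71	21319.16	Chr11	28114223	28116745	exon count exceeds the 0-6 intron range stated in the running text
GrPRX5	Gorai.011G204600.1	PRX6	4	219	5.98	24498.87	Chr11	49579270	49580743
GrPRX6	Gorai.002G243200.1	PRX2	1	227	9.24	24170.9	Chr2	60733892	60734923
GrPRX7	Gorai.004G280800.1	TPX	3	162	5.58	17196.76	Chr4	61267661	61269611
GrPRX8	Gorai.004G285400.1	PRXQ	4	216	9.7	23793.27	Chr4	61634457	61636274
GaPRX1	Ga05G1380	TPX	3	162	5.78	17500.12	Chr05	12175377	12176307
GaPRX2	Ga10G1482	PRX5	5	198	8.98	21445.49	Chr10	80207013	80208997
GaPRX3	Ga05G0262	TPX	3	163	5.58	17538.2	Chr05	2267143	2271319
GaPRX4	Ga04G0982	PRX1	7	265	6.19	29045.27	Chr04	36972413	36976371
GaPRX5	Ga02G1606	PRX2	1	227	9.1	24135.81	Chr02	97187166	97187849
GaPRX6	Ga08G2895	PRXQ	4	216	9.7	23846.33	Chr08	128777936	128779888
GaPRX7	Ga08G2842	TPX	3	162	5.58	17196.76	Chr08	128370617	128372047
GaPRX8	Ga10G0941	PRX6	5	219	5.96	22794.86	Chr10	20870875	20872058
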