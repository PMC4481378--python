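chrom	category	n_genes	n_snps
1	CSCWR	607	4664
1	SCR	2045	5197
1	AGCR	29	154
1	MCR	1	1
2	CSCWR	480	2718
2	SCR	1787	3250
2	AGCR	13	59
2	MCR	7	40
3	CSCWR	547	3000
3	SCR	1888	3852
3	AGCR	27	172
3	MCR	4	20
4	CSCWR	336	1548
4	SCR	1383	2054
4	AGCR	18	170
4	MCR	3	4
5	CSCWR	297	1914
5	SCR	1329	2236
5	AGCR	16	109
5	MCR	11	38
6	CSCWR	313	2292
6	SCR	1302	3050
6	AGCR	22	145
6	MCR	4	15
7	CSCWR	290	1098
7	SCR	1259	1147
7	AGCR	9	48
7	MCR	12	41
8	CSCWR	214	1022
8	SCR	1199	1454
8	AGCR	16	102
8	MCR	0	0
9	CSCWR	205	988
9	SCR	947	1337
9	AGCR	7	41
9	MCR	13	97
10	CSCWR	137	797
10	SCR	327	339
10	AGCR	11	35
10	MCR	20	113
11	CSCWR	143	999
11	SCR	789	1310
11	AGCR	18	120
11	MCR	42	249
12	CSCWR	141	1176
12	SCR	704	775
12	AGCR	8	61
12	MCR	0	0
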