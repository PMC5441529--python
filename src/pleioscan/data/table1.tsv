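snp_id	snp_alias	chrom	pos	gene	region	allele	ra_or	ra_p	sz_or	sz_p
rs3130564	rs3130564	6	31101674	PSORS1C1	intron	T/C	1.23	4.60E-29	0.92969	1.01E-07
rs1050420	rs116597504	6	31239518	HLA-C	exon	T/C	0.9	1.00E-13	1.0709	3.87E-08
rs2524084	rs114208039	6	31241639	HLA-B	intron	A/G	0.83	1.40E-43	1.06855	3.94E-07
rs1634791	rs114802770	6	31276777	HLA-B	intron	A/G	1.15	8.60E-19	0.9366	1.70E-07
rs9265341	rs142174523	6	31294290	HLA-B	intron	A/G	1.32	3.50E-36	0.92663	3.70E-07
rs9265451	rs116690305	6	31296529	HLA-B	intron	A/G	1.3	1.90E-09	0.9209	5.46E-08
rs6902116	rs114876567	6	31300286	HLA-B	intron	A/G	0.85	6.00E-25	1.07778	9.29E-09
rs2442732	rs115437294	6	31313042	HLA-B	intron	A/T	0.89	6.30E-14	1.09286	2.10E-10
rs709055	rs709055	6	31324151	HLA-B	exon	T/C	1.11	6.70E-11	0.93277	3.59E-08
rs12721827	rs12721827	6	31324210	HLA-B	exon	A/G	0.88	9.30E-13	1.07466	2.19E-07
rs1131163	rs1131163	6	31324888	HLA-B	exon	T/G	0.86	4.90E-26	1.07058	1.42E-08
rs2596544	rs139099016	6	31329291	HLA-B	flanking	A/T	1.2	2.60E-31	0.8996	8.22E-13
rs2428492	rs149497261	6	31329302	HLA-B	flanking	T/C	1.09	1.30E-10	0.93361	3.56E-09
rs9267068	rs9267068	6	31397521	HCP5	intron	A/G	0.73	1.30E-38	1.09286	3.85E-07
rs2855812	rs2855812	6	31472720	MICB	intron	T/G	1.17	3.00E-23	0.9352	1.22E-07
rs1265888	rs1265888	6	32066447	TNXB	intron	A/G	1.19	5.20E-22	0.90041	1.90E-11
rs915894	rs114346832	6	32190390	NOTCH4	exon	T/G	0.89	2.10E-17	1.07423	1.23E-08
rs2073045	rs115663894	6	32339548	C6orf10	exon	A/G	1.5	3.70E-151	0.92561	6.32E-08
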