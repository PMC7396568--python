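snp_id	gene	chrom	pos	ref	alt	alt_freq	phenotype	subgroup	or_exp	p_exp	hr_out	hr_ci_low	hr_ci_high	p_out
rs13431652	G6PC2	2	169753415	T	C	0.30	FG	overall	0.79	6.99e-09	1.07	0.96	1.19	0.244
rs560887	G6PC2	2	169763148	T	C	0.29	FG	high-fat	1.28	6.12e-09	0.88	0.78	0.99	0.027
rs117911989	MKLN1	7	130969793	G	A	0.05	FG	active	1.98	3.97e-08	0.56	0.34	0.91	0.020
rs7273292	NKX2-2	20	21473362	T	C	0.01	FG	active	3.37	4.35e-08	1.09	0.54	2.18	0.813
rs10919774	NR5A2	1	199907716	G	A	0.95	FI	obese	1.98	2.53e-08	0.87	0.57	1.34	0.531
rs722025	MTRR	5	8108012	G	A	0.75	FI	inactive	1.28	3.73e-08	0.59	0.40	0.89	0.011
rs6683451	PLA2G4A	1	187292608	A	C	0.11	FI	low-fat	3.16	4.86e-08	1.88	0.24	14.95	0.552
rs77772624	PABPC1P2	2	147499474	A	C	0.001	HOMA-IR	overall	29.65	4.96e-09	1.01	0.25	4.09	0.987
rs77772624	PABPC1P2	2	147499474	A	C	0.001	HOMA-IR	high-fat	28.92	9.36e-09	0.54	0.08	3.84	0.535
rs13277245	MSC	8	72606942	A	G	0.18	HOMA-IR	low-fat	29.57	4.92e-08	1.37	0.83	2.27	0.224
rs113847670	DOCK1	10	128874679	C	T	0.04	HOMA-IR	low-fat	9.18	2.85e-08	0.41	0.11	1.60	0.201
rs17254590	LINC00460	13	107037344	G	C	0.02	HOMA-IR	overall	2.52	2.40e-08	0.64	0.09	4.69	0.661
rs17254590	LINC00460	13	107037344	G	C	0.02	HOMA-IR	high-fat	2.67	8.86e-09	0.66	0.09	4.87	0.685
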