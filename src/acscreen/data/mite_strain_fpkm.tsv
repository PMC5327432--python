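category	gene_id	annotation_id	fpkm_R1	fpkm_R2	fpkm_W1	fpkm_W2	fold_R1_W1	fold_R2_W1	fold_R1_W2	fold_R2_W2
cytochrome P450	CL86.Contig9	tetur27g00340	1.18	1.4	0	0	—	—	—	—
cytochrome P450	CL86.Contig15	tetur27g00340	3.27	3.54	0.73	1.08	2.16	2.28	1.60	1.72
cytochrome P450	CL1948.Contig1	tetur36g00920	4.59	4.28	1.42	1.40	1.69	1.59	1.71	1.61
cytochrome P450	Unigene8610	tetur03g05010	3.54	4.64	1.13	1.05	1.65	2.04	1.75	2.14
cytochrome P450	Unigene10928	tetur07g06460	3.62	6.95	0.34	0.88	3.41	4.35	2.04	2.98
cytochrome P450	Unigene12355	tetur11g05000	1.02	1.39	0.40	0.36	1.36	1.82	1.50	1.95
glutathione S-transferase	CL1160.Contig1	tetur03g07920	32.77	36.02	6.83	7.23	2.26	2.40	2.18	2.32
glutathione S-transferase	CL1160.Contig2	tetur26g02802	16.83	29.62	3.30	3.00	2.35	3.17	2.49	3.30
glutathione S-transferase	CL1160.Contig4	tetur26g01450	15.26	21.88	4.97	2.99	1.62	2.14	2.35	2.87
glutathione S-transferase	CL2286.Contig8	tetur29g00220	9.19	13.57	2.67	1.20	1.78	2.35	2.93	3.50
glutathione S-transferase	Unigene4639	tetur26g01460	5.31	7.05	0.73	0.34	2.87	3.28	3.96	4.37
glutathione S-transferase	Unigene4640	tetur03g07920	5.25	6.92	0.62	0.38	3.09	3.48	3.78	4.18
glutathione S-transferase	Unigene4642	tetur03g07920	3.63	6.60	0.37	0.25	3.29	4.15	3.83	4.70
glutathione S-transferase	Unigene4643	tetur03g07920	3.90	6.59	0.43	0.32	3.17	3.93	3.62	4.37
carboxylesterase	CL187.Contig8	tetur11g01570	0.08	0.59	0	0	—	—	—	—
carboxylesterase	Unigene1530	tetur11g01570	0.50	3.25	0	0.02	—	—	4.46	7.16
carboxylesterase	Unigene1585	tetur11g01570	0.36	1.87	0	0.01	—	—	5.92	8.31
carboxylesterase	Unigene1594	tetur11g01570	0.08	0.67	0	0.01	—	—	3.14	6.12
carboxylesterase	Unigene1597	tetur11g01570	0.13	0.72	0	0.01	—	—	4.52	6.96
carboxylesterase	Unigene1626	tetur11g01570	0.09	0.68	0	0.01	—	—	3.13	6.11
carboxylesterase	CL1124.Contig1	tetur35g00210	11.44	12.23	4.08	3.99	1.49	1.59	1.52	1.62
carboxylesterase	CL1837.Contig2	tetur01g08680	23.37	5.87	1.36	0.94	4.10	2.11	4.64	2.65
ABC transporter	CL210.Contig1	tetur40g00010	51.20	43.98	20.79	16.27	1.30	1.08	1.65	1.43
ABC transporter	CL210.Contig5	tetur03g09800	6.37	4.57	1.41	1.01	2.17	1.69	2.65	2.17
ABC transporter	CL210.Contig11	tetur03g09800	4.14	4.52	1.25	1.24	1.73	1.85	1.73	1.86
ABC transporter	CL210.Contig17	tetur40g00010	7.18	5.47	1.69	1.30	2.09	1.70	2.47	2.07
ABC transporter	CL210.Contig18	tetur40g00010	7.14	5.06	1.66	1.17	2.11	1.61	2.61	2.11
ABC transporter	CL1338.Contig2	tetur32g01330	6.06	6.62	2.45	1.63	1.31	1.43	1.90	2.02
ABC transporter	CL1587.Contig1	tetur09g04610	8.90	11.49	3.80	3.17	1.23	1.60	1.49	1.86
ABC transporter	CL2055.Contig1	tetur11g04030	1.00	1.06	0.25	0.20	2.00	2.08	2.33	2.40
ABC transporter	CL2870.Contig2	tetur20g02610	6.13	7.85	2.87	2.55	1.10	1.45	1.27	1.62
ABC transporter	CL4679.Contig2	tetur32g00490	22.32	28.06	10.50	10.49	1.09	1.42	1.09	1.42
ABC transporter	Unigene7691	tetur04g07910	1.40	3.04	0.55	0.28	1.35	2.47	2.31	3.43
DnaJ	CL1638.Contig1	tetur01g13410	32.36	36.63	7.41	6.48	2.13	2.31	2.32	2.50
DnaJ	CL1638.Contig2	tetur01g13410	9.93	8.46	0.67	0.56	3.90	3.67	4.15	3.92
DnaJ	CL1638.Contig4	tetur01g13400	90.78	80.10	34.52	26.66	1.39	1.21	1.77	1.59
DnaJ	CL2475.Contig2	tetur08g07280	10.06	6.72	0.99	1.45	3.34	2.76	2.80	2.22
DnaJ	CL4208.Contig1	tetur15g02000	10.69	21.12	2.67	1.85	2.00	2.99	2.53	3.51
DnaJ	Unigene11337	tetur13g02530	10.04	12.38	4.72	4.05	1.09	1.39	1.31	1.61
DnaJ	Unigene14563	tetur97g00050	434.42	1758.76	46.20	113.91	3.23	5.25	1.93	3.95
Hsp27	Unigene9853	tetur22g01530	57.63	87.84	9.55	9.72	2.59	3.20	2.57	3.18
Hsp60	CL4306.Contig1	tetur02g03850	12.89	13.24	3.59	3.36	1.84	1.88	1.94	1.98
Hsp60	CL4306.Contig2	tetur02g03850	9.72	8.03	2.99	2.78	1.70	1.43	1.81	1.53
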