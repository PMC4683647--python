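section	cross_type	dam	sire	n_total_printed	n_female	n_herm	expected_printed	chi2_printed	p_printed	model_ratio	preset_ratio	ratio_note	chi2_flag	note
A	H-SELF	NM-LNF23	NM-LNF23	53	9	44	1:3	2.70	0.10	1:3			irreproducible	
A	H-SELF	NM-LNF25	NM-LNF25	53	17	36	1:3	1.42	0.23	1:3				
A	H-SELF	NM-LNF14	NM-LNF14	30	15	15	1:3	4.6	0.03	7:9		alt_in_text	irreproducible	source table footnote: 9:7 alternative tested in text
A	F x H	NM-LNF26	NM-LNF23	12	4	8	1:1	1.33	0.25	1:1				
A	F x H	NM-LNF26	NM-LNF25	50	29	21	1:1	1.28	0.26	1:1				
A	F x H	NM-LNF26	NM-LNF14	10	6	4	1:1	0.40	0.53	1:1				
A	F x H	NM-LNF2	NM-LNF23	20	11	9	1:1	0.20	0.65	1:1				
A	F x H	NM-LNF2	NM-LNF25	42	20	22	1:1	0.10	0.76	1:1				
A	F x H	NM-LNF2	NM-LNF14	17	7	10	1:1	0.53	0.47	1:1				
A	F x H	NM-LNF4	NM-LNF23	40	17	23	1:1	0.90	0.34	1:1				
A	F x H	NM-LNF4	NM-LNF25	29	11	18	1:1	1.69	0.19	1:1				
A	F x H	NM-LNF4	NM-LNF14	7	3	4	1:1	0.14	0.71	1:1				printed statistic despite n<10
A	H x H	NM-LNF23	NM-LNF25	4	1	3	1:3	NA	NA	1:3				
A	H x H	NM-LNF25	NM-LNF23	22	5	17	1:3	0.06	0.80	1:3				
A	H x H	NM-LNF14	NM-LNF23	27	5	22	1:3	0.61	0.43	1:3				
A	H x H	NM-LNF14	NM-LNF25	2	1	1	1:3	NA	NA	1:3				
A	H x H	NM-LNF25	NM-LNF14	0	0	0	NA	NA	NA	1:3				zero progeny
A	H x H	NM-LNF23	NM-LNF14	0	0	0	NA	NA	NA	1:3				zero progeny
B	H-SELF	OR-MRD45	OR-MRD45	16	3	13	1:3	0.33	0.56	1:3				
B	H-SELF	OR-MRD61	OR-MRD61	43	0	43	1:3	14.33	0.00	0:1		alt_in_text		source table footnote: 0:1 alternative tested in text
B	H-SELF	OR-MRD93	OR-MRD93	39	8	31	1:3	0.42	0.52	1:3				
B	F x H	OR-MRD27	OR-MRD45	18	10	8	1:1	0.22	0.64	1:1				
B	F x H	OR-MRD27	OR-MRD61	31	11	20	1:1	2.61	0.11	1:1				
B	F x H	OR-MRD27	OR-MRD93	19	11	8	1:1	0.47	0.49	1:1				
B	F x H	OR-MRD30	OR-MRD45	11	5	6	1:1	0.09	0.76	1:1				
B	F x H	OR-MRD30	OR-MRD61	23	11	12	1:1	0.04	0.83	1:1				
B	F x H	OR-MRD30	OR-MRD93	19	8	11	1:1	0.47	0.49	1:1				
B	F x H	OR-MRD90	OR-MRD45	25	13	12	1:1	0.04	0.84	1:1				
B	F x H	OR-MRD90	OR-MRD61	28	10	18	1:1	2.29	0.13	1:1				
B	F x H	OR-MRD90	OR-MRD93	38	15	23	1:1	1.68	0.19	1:1				
B	H x H	OR-MRD45	OR-MRD61	11	0	11	0:1	0.00	NA	0:1				
B	H x H	OR-MRD61	OR-MRD45	14	1	13	0:1	0.00	NA	0:1			anomalous_female	one anomalous female noted in text
B	H x H	OR-MRD61	OR-MRD93	20	0	20	0:1	0.00	NA	0:1				
B	H x H	OR-MRD93	OR-MRD61	0	0	0	NA	NA	NA	0:1				zero progeny
B	H x H	OR-MRD45	OR-MRD93	7	0	7	1:3	2.33	NA	0:1		tested_not_predicted		printed ratio is a tested hypothesis, not the inferred-genotype prediction
B	H x H	OR-MRD93	OR-MRD45	4	0	4	1:3	NA	NA	0:1		tested_not_predicted		printed ratio is a tested hypothesis, not the inferred-genotype prediction
C	F x H	OR-MRD27	NM-LNF23	17	13	4	1:1	4.76	0.03	1:1		alt_in_text		source table footnote: female-skew discussed in text
C	F x H	OR-MRD27	NM-LNF25	35	18	17	1:1	0.03	0.87	1:1				
C	F x H	OR-MRD27	NM-LNF14	14	10	4	1:1	2.57	0.11	1:1				
C	F x H	OR-MRD30	NM-LNF23	26	15	11	1:1	0.62	0.43	1:1				
C	F x H	OR-MRD30	NM-LNF25	33	20	13	1:1	1.48	0.22	1:1				
C	F x H	OR-MRD30	NM-LNF14	16	9	7	1:1	0.25	0.62	1:1				
C	F x H	OR-MRD90	NM-LNF23	44	24	20	1:1	0.36	0.55	1:1				
C	F x H	OR-MRD90	NM-LNF25	46	20	26	1:1	0.78	0.38	1:1				
C	F x H	OR-MRD90	NM-LNF14	39	17	22	1:1	0.64	0.42	1:1				
C	F x H	NM-LNF26	OR-MRD45	13	0	13	0:1	0.00	NA	0:1				
C	F x H	NM-LNF26	OR-MRD61	15	0	15	0:1	0.00	NA	0:1				
C	F x H	NM-LNF26	OR-MRD93	21	15	6	1:1	3.86	0.05	1:1	2:1	alt_in_text		source table footnote: 2:1 lethality alternative tested in text
C	F x H	NM-LNF2	OR-MRD45	18	0	18	0:1	0.00	NA	0:1				
C	F x H	NM-LNF2	OR-MRD61	5	0	5	0:1	0.00	NA	0:1				
C	F x H	NM-LNF2	OR-MRD93	28	21	7	1:1	7.00	0.01	1:1	2:1	alt_in_text		source table footnote: 2:1 lethality alternative tested in text
C	F x H	NM-LNF4	OR-MRD45	14	0	14	0:1	0.00	NA	0:1				
C	F x H	NM-LNF4	OR-MRD61	15	0	15	0:1	0.00	NA	0:1				
C	F x H	NM-LNF4	OR-MRD93	52	35	17	1:1	6.23	0.01	1:1	2:1	alt_in_text		source table footnote: 2:1 lethality alternative tested in text
C	H x H	OR-MRD45	NM-LNF23	29	0	29	0:1	0.00	NA	0:1				
C	H x H	OR-MRD45	NM-LNF25	17	0	18	0:1	0.00	NA	0:1				printed total 17 contradicts counts 0+18; counts kept as printed
C	H x H	OR-MRD45	NM-LNF14	0	0	0	NA	NA	NA	1:3				zero progeny
C	H x H	OR-MRD61	NM-LNF23	25	0	25	0:1	0.00	NA	0:1				
C	H x H	OR-MRD61	NM-LNF25	15	0	15	0:1	0.00	NA	0:1				
C	H x H	OR-MRD93	NM-LNF23	27	6	21	1:3	0.11	0.08	1:3				
C	H x H	OR-MRD93	NM-LNF25	3	0	3	1:3	NA	NA	1:3				
C	H x H	OR-MRD93	NM-LNF14	0	0	0	NA	NA	NA	1:3				zero progeny
C	H x H	NM-LNF23	OR-MRD45	0	0	0	NA	NA	NA	0:1				zero progeny
C	H x H	NM-LNF23	OR-MRD61	1	0	1	0:1	NA	NA	0:1				
C	H x H	NM-LNF23	OR-MRD93	4	2	2	1:3	NA	NA	1:3				
C	H x H	NM-LNF25	OR-MRD45	0	0	0	NA	NA	NA	0:1				zero progeny
C	H x H	NM-LNF25	OR-MRD61	0	0	0	NA	NA	NA	0:1				zero progeny
C	H x H	NM-LNF25	OR-MRD93	0	0	0	NA	NA	NA	1:3				zero progeny
C	H x H	NM-LNF14	OR-MRD45	4	2	2	1:3	NA	NA	1:3				
C	H x H	NM-LNF14	OR-MRD61	3	0	3	0:1	NA	NA	0:1				
C	H x H	NM-LNF14	OR-MRD93	0	0	0	NA	NA	NA	1:3				zero progeny
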