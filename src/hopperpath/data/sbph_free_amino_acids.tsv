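analyte	S0	S0_se	R0	R0_se	S6	S6_se	R6	R6_se	printed_pct_S6_S0	printed_pct_R6_R0
Isoleucine	27.7	2.7	43.5	4.2	1.9	0.4	12.5	1.4	-93.1	-71.3
Citrulline	12	1.3	13	1.4	2.4	0.3	7	0.8	-80.0	-46.2
Lysine	27	2.8	31.1	3.4	6.3	0.6	9.8	0.9	-76.7	-68.5
Methionine	11.80	0.59	3.60	0.28	11.03	0.67	0.42	0.04	-69.5	-96.2
Cystine	11.44	0.99	5.97	0.45	24.47	1.79	10.14	0.91	-47.8	-58.6
Valine	23.4	1.9	23.1	2.5	13.6	1.5	16.8	1.3	-41.9	-27.3
Aspartic acid	26.95	3.59	15.68	1.23	23.70	2.25	21.65	1.94	-41.8	-8.6
Cystathionine	2.73	0.25	1.74	0.13	4.58	0.68	0.39	0.03	-36.3	-91.5
Ornithine	2.1	0.1	3.6	0.1	1.4	0.1	2.9	0.2	-33.3	-19.4
β-Aminoisobutyric Acid	3.6	0.3	5	0.4	2.7	0.2	1.8	0.2	-25.0	-64.0
Ethanolamine	11	1.3	9.1	1	8.7	0.9	7.5	0.8	-20.9	-17.6
Phenylalanine	18.5	1.8	7.5	0.3	3.2	0.3	7.9	0.5	-82.7	5.3
Arginine	90.4	10.9	30	3.4	18.6	1.8	46.7	4.8	-79.4	55.7
β-Alanine	6.4	0.3	5.5	0.4	3.9	0.4	8.1	0.6	-39.1	47.3
Serine	7.19	0.71	4.43	0.31	2.87	0.26	5.46	0.45	-38.4	90.2
Glycine	7.7	1	9.3	1.6	5.2	0.4	11.1	1.2	-32.5	19.4
Leucine	2.2	0.1	6.3	0.2	1.5	0.1	11.3	1.3	-31.8	79.4
Glutamic Acid	114.3	8.8	143.8	14.2	81.9	8.9	160.4	15.4	-28.3	11.5
Threonine	2.9	0.3	1.9	0.2	2.1	0.2	3.6	0.3	-27.6	89.5
Alanine	10	1.1	10.9	1.2	8.9	0.4	20	0.8	-11.0	83.5
α-Amino-n-butyric Acid	2.5	0.2	3.6	0.2	4	0.2	2.9	0.2	60.0	-19.4
Tyrosine	4.7	0.3	3.7	0.3	11.3	1.2	14.7	1.2	140.4	297.3
α-Aminoadipic Acid	7.9	0.6	11.5	1.4	14.3	0.8	28.4	1.2	81.0	147.0
γ-Amino-n-butyric Acid	4.4	0.4	2.3	0.2	6.2	0.5	22.9	2	40.9	895.7
Proline	5	0.3	2.6	0.2	5.7	0.3	5.3	0.4	14.0	103.8
Total	443.7	40.7	434.1	40.9	235.3	21.1	439.6	37.9	-47.0	1.3
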