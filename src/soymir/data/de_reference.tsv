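sequence	mirna	log2_MON_A32	flag_MON_A32	log2_DP3_JAC	flag_DP3_JAC	log2_A32_JAC	flag_A32_JAC	names
TCTCATTCCATACATCGTCTGA	miR1507a	-1.03	down	0.49	none	0.88	none	gma-miR1507a
AGGGATAGGTAAAACAACTACT	miR1510b-5p	-1.10	down	-0.34	none	0.98	none	gma-miR1510b-5p
AACCAGGCTCTGATACCATG	miR1511	0.06	none	2.59	up	2.07	up	gma-miR1511
TTGACAGAAGATAGAGAGCAC	miR156c	-0.44	none	0.70	none	1.07	up	gma-miR156c,d,e,i,j,l,m
TCGGACCAGGCTTCATTCCCC	miR166a-3p	-1.10	down	0.44	none	1.00	up	gma-miR166a-3p,b,c-3p,d,e,f,g,n,o,i-3p
TCTCGGACCAGGCTTCATTCC	miR166h-3p	-1.29	down	0.66	none	1.46	up	gma-miR166h-3p,k
TCTCGGACCAGGCTTCATTC	miR166u	-1.36	down	0.41	none	0.95	none	gma-miR166u
GGAGATGGGAGGGTCGGTAAAG	miR2118a-5p	-0.38	none	-0.46	none	-1.10	down	gma-miR2118a-5p,b-5p
TTGGACTGAAGGGAGCTCCC	miR319a	-1.21	down	0.62	none	1.21	up	gma-miR319a,b,e
AAGCTCAGGAGGGATAGCGCC	miR390a-5p	-1.94	down	0.21	none	1.58	up	gma-miR390a-5p,f,g
AGCTCAGGAGGGATAGCGCC	miR390e	-1.77	down	0.31	none	2.00	up	gma-miR390e
TTCCACAGCTTTCTTGAACTT	miR396b-5p	-1.00	down	0.30	none	0.88	none	gma-miR396b-5p,c
TGTGTTCTCAGGTCGCCCCTG	miR398c	-0.42	none	2.49	up	2.79	up	gma-miR398c
TGTTGCGGGTATCTTTGCCTC	miR4412-5p	0.36	none	-0.12	none	-1.57	down	gma-miR4412-5p
TCTTCCCTACACCTCCCATACC	miR482b-3p	-1.27	down	0.21	none	1.27	up	gma-miR482b-3p,d-3p
TTCCCAATTCCGCCCATTCCT	miR482c-3p	-0.93	none	-1.17	down	1.26	up	gma-miR482c-3p
TGAAGATTTGAAGAATTTGGGA	miR5376	-0.46	none	-0.36	none	-1.19	down	gma-miR5376
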