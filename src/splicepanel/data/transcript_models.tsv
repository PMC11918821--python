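# Synthetic transcript models for worked examples and simulations.
# Exon boundaries carrying published c. coordinates are exact (PTEN exon 3 =
# c.165-209; MLH1 exon 3 ends c.306, exon 10 = c.791-884; BRCA2-window exon 2
# = c.68-316; MSH2 exon 7 = c.1077-1276). Remaining exon lengths and all
# intron lengths are invented stand-ins; BRCA2 models only the 5-exon capture
# window around its exon 3 (window-local exon numbering).
gene	transcript_id	exon_index	exon_length	intron_length_after	cds_start_offset	cds_length
PTEN	NM_000314.8	1	79	300	0	1212
PTEN	NM_000314.8	2	85	250	0	1212
PTEN	NM_000314.8	3	45	400	0	1212
PTEN	NM_000314.8	4	44	350	0	1212
PTEN	NM_000314.8	5	239	200	0	1212
PTEN	NM_000314.8	6	142	150	0	1212
PTEN	NM_000314.8	7	167	220	0	1212
PTEN	NM_000314.8	8	225	180	0	1212
PTEN	NM_000314.8	9	186		0	1212
MLH1	NM_000249.4	1	116	350	0	1200
MLH1	NM_000249.4	2	91	280	0	1200
MLH1	NM_000249.4	3	99	470	0	1200
MLH1	NM_000249.4	4	74	260	0	1200
MLH1	NM_000249.4	5	73	310	0	1200
MLH1	NM_000249.4	6	92	240	0	1200
MLH1	NM_000249.4	7	43	220	0	1200
MLH1	NM_000249.4	8	89	330	0	1200
MLH1	NM_000249.4	9	113	290	0	1200
MLH1	NM_000249.4	10	94	380	0	1200
MLH1	NM_000249.4	11	154	270	0	1200
MLH1	NM_000249.4	12	162		0	1200
BRCA2	NM_000059.4	1	167	900	100	651
BRCA2	NM_000059.4	2	249	700	100	651
BRCA2	NM_000059.4	3	109	500	100	651
BRCA2	NM_000059.4	4	107	400	100	651
BRCA2	NM_000059.4	5	119		100	651
MSH2	NM_000251.3	1	211	420	0	1680
MSH2	NM_000251.3	2	155	360	0	1680
MSH2	NM_000251.3	3	279	300	0	1680
MSH2	NM_000251.3	4	147	340	0	1680
MSH2	NM_000251.3	5	150	280	0	1680
MSH2	NM_000251.3	6	134	390	0	1680
MSH2	NM_000251.3	7	200	310	0	1680
MSH2	NM_000251.3	8	110	260	0	1680
MSH2	NM_000251.3	9	150	230	0	1680
MSH2	NM_000251.3	10	144		0	1680
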