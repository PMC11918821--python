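gene	transcript_id	hgvs_c	exons	chimeric_reads	assigned_class
ATM	NM_000051.4	c.(8850+1_8855-1)_(*1_?)dup	62-63	No	3
ATM	NM_000051.4	c.(2466+1_2467-1)_(8850+1_8851-1)dup	17-61	Yes	5
MSH2	NM_000251.3	c.(1076+1_1077-1)_(1276+1_1277-1)dup	7-7	Yes	5
PMS2	NM_000535.7	c.(1144+1_1145-1)_(2174+1_2175-1)dup	11-12	Yes	5
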