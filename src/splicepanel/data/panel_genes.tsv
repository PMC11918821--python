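symbol	transcript_id
AIP	NM_003977.4
APC	NM_000038.6
ATM	NM_000051.4
BAP1	NM_004656.4
BMPR1A	NM_004329.3
BRCA1	NM_007294.4
BRCA2	NM_000059.4
BRIP1	NM_032043.3
CASR	NM_000388.4
CDC73	NM_024529.5
CDH1	NM_004360.5
CDK4	NM_000075.4
CDKN2A	NM_000077.5
CHEK2	NM_007194.4
EPCAM	NM_002354.3
FH	NM_000143.4
FLCN	NM_144997.7
MAX	NM_002382.5
MC1R	NM_002386.4
MEN1	NM_130799.2
MET	NM_001127500.3
MITF	NM_000248.4
MLH1	NM_000249.4
MSH2	NM_000251.3
MSH6	NM_000179.3
MUTYH	NM_001048174.2
NBN	NM_002485.5
NF1	NM_000267.3
NF2	NM_000268.4
PALB2	NM_024675.4
PMS2	NM_000535.7
POLD1	NM_001256849.1
POLE	NM_006231.4
PTEN	NM_000314.8
RAD51C	NM_058216.3
RAD51D	NM_002878.4
RET	NM_020975.6
SDHA	NM_004168.4
SDHAF2	NM_017841.4
SDHB	NM_003000.3
SDHC	NM_003001.5
SDHD	NM_003002.4
SMAD4	NM_005359.6
STK11	NM_000455.5
TMEM127	NM_017849.4
TP53	NM_000546.6
VHL	NM_000551.4
WRN	NM_000553.6
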