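# Bijective map between the short protein symbols used in the migration
# network / attractor table and official gene symbols.
short	symbol
PCM1	PCM1
BBS4	BBS4
CDK5	CDK5
DIXC1	DIXDC1
NDEL1	NDEL1
A4	APP
LIS1	PAFAH1B1
DAB1	DAB1
CC141	CCDC141
MYH2	MYH2
ZN365	ZNF365
GSK3B	GSK3B
DISC1	DISC1
SOX10	SOX10
FOXD3	FOXD3
RHEB	RHEB
ACTB	ACTB
AKT1	AKT1
GRDN	CCDC88A
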