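# Synthetic emulation of a ChEA-style snapshot: direct TF -> target-gene
# regulations among the migration-network genes (DISC1 excluded here: every
# critical TF also upregulates DISC1, which is handled by the per-FM wiring,
# not by loop-to-FM assignment).
regulator	regulator_type	target	target_type	source_db	evidence
STAT3	TF	GSK3B	gene	ChEA	ChIP-seq
TAL1	TF	PCM1	gene	ChEA	ChIP-seq
TAL1	TF	BBS4	gene	ChEA	ChIP-chip
TCF3	TF	PCM1	gene	ChEA	ChIP-seq
TCF3	TF	BBS4	gene	ChEA	ChIP-seq
CCND1	TF	ZNF365	gene	ChEA	ChIP-chip
CREB1	TF	NDEL1	gene	ChEA	ChIP-seq
KLF4	TF	PAFAH1B1	gene	ChEA	ChIP-seq
ZEB1	TF	SOX10	gene	ChEA	ChIP-seq
MYC	TF	CDK5	gene	ChEA	ChIP-seq
E2F1	TF	CCDC141	gene	ChEA	ChIP-chip
NFKB1	TF	AKT1	gene	ChEA	ChIP-seq
FOXO1	TF	DAB1	gene	ChEA	ChIP-seq
STAT3	TF	VEGFA	gene	ChEA	ChIP-seq
MYC	TF	CDKN1A	gene	ChEA	ChIP-seq
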