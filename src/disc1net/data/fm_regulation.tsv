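# Regulatory wiring of the per-FM perturbation networks (synthetic emulation
# of the published comprehensive network model: three critical miRNA-TF
# feedback loops -- miR223-TAL1, miR320a-TCF3, miR155-STAT3 and the other
# STAT3-loop miRNAs -- plus their direct gene targets in each FM and the
# protein-layer repressions exerted by DISC1).
# fm=ALL rows are shared by every FM network (loop wiring + DISC1 regulation).
# regulator_type "protein" marks a protein-layer repression (target rule gains
# a "& !regulator" term).
fm	regulator	regulator_type	target	target_type
ALL	miR223	miRNA	TAL1	TF
ALL	miR320a	miRNA	TCF3	TF
ALL	miR155	miRNA	STAT3	TF
ALL	miR106a	miRNA	STAT3	TF
ALL	miR20a	miRNA	STAT3	TF
ALL	miR17	miRNA	STAT3	TF
ALL	miR103a	miRNA	STAT3	TF
ALL	miR125b	miRNA	STAT3	TF
ALL	miR20b	miRNA	STAT3	TF
ALL	TAL1	TF	miR223	miRNA
ALL	TCF3	TF	miR320a	miRNA
ALL	STAT3	TF	miR155	miRNA
ALL	STAT3	TF	miR106a	miRNA
ALL	STAT3	TF	miR20a	miRNA
ALL	STAT3	TF	miR17	miRNA
ALL	STAT3	TF	miR103a	miRNA
ALL	STAT3	TF	miR125b	miRNA
ALL	STAT3	TF	miR20b	miRNA
ALL	TAL1	TF	DISC1	gene
ALL	TCF3	TF	DISC1	gene
ALL	STAT3	TF	DISC1	gene
FM1	TAL1	TF	PCM1	gene
FM1	TCF3	TF	PCM1	gene
FM1	STAT3	TF	PCM1	gene
FM1	TAL1	TF	BBS4	gene
FM1	TCF3	TF	BBS4	gene
FM1	STAT3	TF	BBS4	gene
FM2	TAL1	TF	PAFAH1B1	gene
FM2	TCF3	TF	PAFAH1B1	gene
FM2	STAT3	TF	PAFAH1B1	gene
FM2	TAL1	TF	ZNF365	gene
FM2	TCF3	TF	ZNF365	gene
FM2	STAT3	TF	ZNF365	gene
FM2	TAL1	TF	GSK3B	gene
FM2	TCF3	TF	GSK3B	gene
FM2	STAT3	TF	GSK3B	gene
FM2	TAL1	TF	NDEL1	gene
FM2	TCF3	TF	NDEL1	gene
FM2	STAT3	TF	NDEL1	gene
FM2	miR106a	miRNA	ZNF365	gene
FM2	miR125b	miRNA	GSK3B	gene
FM2	DISC1	protein	GSK3B	gene
FM3	TAL1	TF	CDK5	gene
FM3	TCF3	TF	CDK5	gene
FM3	STAT3	TF	CDK5	gene
FM3	TAL1	TF	NDEL1	gene
FM3	TCF3	TF	NDEL1	gene
FM3	STAT3	TF	NDEL1	gene
FM3	miR155	miRNA	CDK5	gene
FM4	TAL1	TF	APP	gene
FM4	TCF3	TF	APP	gene
FM4	STAT3	TF	APP	gene
FM4	TAL1	TF	NDEL1	gene
FM4	TCF3	TF	NDEL1	gene
FM4	STAT3	TF	NDEL1	gene
FM4	TAL1	TF	DAB1	gene
FM4	TCF3	TF	DAB1	gene
FM4	STAT3	TF	DAB1	gene
FM4	TAL1	TF	PAFAH1B1	gene
FM4	TCF3	TF	PAFAH1B1	gene
FM4	STAT3	TF	PAFAH1B1	gene
FM4	miR17	miRNA	APP	gene
FM4	miR20b	miRNA	APP	gene
FM4	miR20a	miRNA	DAB1	gene
FM6	TAL1	TF	AKT1	gene
FM6	TCF3	TF	AKT1	gene
FM6	STAT3	TF	AKT1	gene
FM6	TAL1	TF	ACTB	gene
FM6	TCF3	TF	ACTB	gene
FM6	STAT3	TF	ACTB	gene
FM6	TAL1	TF	CCDC88A	gene
FM6	TCF3	TF	CCDC88A	gene
FM6	STAT3	TF	CCDC88A	gene
FM6	miR155	miRNA	AKT1	gene
FM7	STAT3	TF	FOXD3	gene
FM7	DISC1	protein	SOX10	gene
FM7	DISC1	protein	FOXD3	gene
FM8	TAL1	TF	RHEB	gene
FM8	TCF3	TF	RHEB	gene
FM8	STAT3	TF	RHEB	gene
FM8	miR155	miRNA	RHEB	gene
FM8	DISC1	protein	RHEB	gene
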