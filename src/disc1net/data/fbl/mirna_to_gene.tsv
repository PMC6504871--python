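# Synthetic emulation of a miRWalk-style snapshot: validated miRNA -> gene
# targeting among the migration-network genes.
regulator	regulator_type	target	target_type	source_db	evidence
hsa-miR-155-5p	miRNA	CDK5	gene	miRWalk	validated
hsa-miR-155-5p	miRNA	AKT1	gene	miRWalk	validated
hsa-miR-155-5p	miRNA	RHEB	gene	miRWalk	validated
hsa-miR-17-5p	miRNA	APP	gene	miRWalk	validated
hsa-miR-20a-5p	miRNA	DAB1	gene	miRWalk	validated
hsa-miR-20b-5p	miRNA	APP	gene	miRWalk	validated
hsa-miR-106a-5p	miRNA	ZNF365	gene	miRWalk	validated
hsa-miR-125b-5p	miRNA	GSK3B	gene	miRWalk	validated
hsa-miR-9-5p	miRNA	BDNF	gene	miRWalk	validated
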