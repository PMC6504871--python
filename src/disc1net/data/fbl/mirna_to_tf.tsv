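# Synthetic emulation of a miRTarBase-style snapshot: experimentally supported
# miRNA -> TF regulations.  Identifiers are raw database-style names; loop
# mining normalizes them (hsa- prefix and arm suffix stripped).
regulator	regulator_type	target	target_type	source_db	evidence
hsa-miR-155-5p	miRNA	STAT3	TF	miRTarBase	luciferase
hsa-miR-17-5p	miRNA	STAT3	TF	miRTarBase	luciferase
hsa-miR-20a-5p	miRNA	STAT3	TF	miRTarBase	western
hsa-miR-20b-5p	miRNA	STAT3	TF	miRTarBase	luciferase
hsa-miR-106a-5p	miRNA	STAT3	TF	miRTarBase	western
hsa-miR-125b-5p	miRNA	STAT3	TF	miRTarBase	luciferase
hsa-miR-103a-3p	miRNA	STAT3	TF	miRTarBase	qPCR
hsa-miR-223-3p	miRNA	TAL1	TF	miRTarBase	luciferase
hsa-miR-320a	miRNA	TCF3	TF	miRTarBase	luciferase
hsa-miR-17-5p	miRNA	CCND1	TF	miRTarBase	luciferase
hsa-miR-20a-5p	miRNA	CCND1	TF	miRTarBase	western
hsa-miR-103a-3p	miRNA	CREB1	TF	miRTarBase	luciferase
hsa-miR-10b-5p	miRNA	KLF4	TF	miRTarBase	luciferase
hsa-miR-200b-3p	miRNA	ZEB1	TF	miRTarBase	luciferase
hsa-miR-200c-3p	miRNA	ZEB1	TF	miRTarBase	luciferase
hsa-miR-34a-5p	miRNA	MYC	TF	miRTarBase	western
hsa-miR-34a-5p	miRNA	E2F1	TF	miRTarBase	luciferase
hsa-miR-106b-5p	miRNA	E2F1	TF	miRTarBase	luciferase
hsa-miR-9-5p	miRNA	NFKB1	TF	miRTarBase	luciferase
hsa-miR-27a-3p	miRNA	FOXO1	TF	miRTarBase	western
hsa-miR-96-5p	miRNA	FOXO1	TF	miRTarBase	luciferase
hsa-miR-21-5p	miRNA	STAT3	TF	miRTarBase	qPCR
hsa-miR-451a	miRNA	GATA1	TF	miRTarBase	luciferase
hsa-miR-124-3p	miRNA	CREB1	TF	miRTarBase	western
hsa-let-7a-5p	miRNA	MYC	TF	miRTarBase	luciferase
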