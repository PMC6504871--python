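# Synthetic emulation of TransmiR/ChIPBase-style snapshots: TF -> miRNA
# transcriptional regulations (stem-loop naming, normalized during mining).
regulator	regulator_type	target	target_type	source_db	evidence
STAT3	TF	hsa-mir-155	miRNA	TransmiR	ChIP
STAT3	TF	hsa-mir-17	miRNA	ChIPBase	ChIP-seq
STAT3	TF	hsa-mir-20a	miRNA	ChIPBase	ChIP-seq
STAT3	TF	hsa-mir-20b	miRNA	ChIPBase	ChIP-seq
STAT3	TF	hsa-mir-106a	miRNA	TransmiR	reporter
STAT3	TF	hsa-mir-125b	miRNA	TransmiR	ChIP
STAT3	TF	hsa-mir-103a	miRNA	ChIPBase	ChIP-seq
TAL1	TF	hsa-mir-223	miRNA	TransmiR	ChIP
TCF3	TF	hsa-mir-320a	miRNA	ChIPBase	ChIP-seq
CCND1	TF	hsa-mir-17	miRNA	ChIPBase	ChIP-seq
CCND1	TF	hsa-mir-20a	miRNA	ChIPBase	ChIP-seq
CREB1	TF	hsa-mir-103a	miRNA	TransmiR	ChIP
KLF4	TF	hsa-mir-10b	miRNA	TransmiR	reporter
ZEB1	TF	hsa-mir-200b	miRNA	TransmiR	ChIP
ZEB1	TF	hsa-mir-200c	miRNA	TransmiR	ChIP
MYC	TF	hsa-mir-34a	miRNA	TransmiR	ChIP
E2F1	TF	hsa-mir-34a	miRNA	ChIPBase	ChIP-seq
E2F1	TF	hsa-mir-106b	miRNA	TransmiR	ChIP
NFKB1	TF	hsa-mir-9	miRNA	TransmiR	ChIP
FOXO1	TF	hsa-mir-27a	miRNA	ChIPBase	ChIP-seq
FOXO1	TF	hsa-mir-96	miRNA	ChIPBase	ChIP-seq
MYC	TF	hsa-mir-26a	miRNA	TransmiR	ChIP
SP1	TF	hsa-mir-29a	miRNA	TransmiR	ChIP
JUN	TF	hsa-mir-101	miRNA	ChIPBase	ChIP-seq
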