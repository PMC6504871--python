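# Synthetic emulation of ChEA/Enrichr enrichment output: 2x2 contingency
# counts per TF (a = TF targets inside the migration gene set, b = TF targets
# outside it, c = set genes not targeted, d = background remainder).  The
# background universe is the enrichment server's, so counts are inputs, not
# recomputed; p-values are computed by the package (one-sided Fisher).
tf	a	b	c	d
STAT3	6	40	13	950
TAL1	3	22	16	960
TCF3	3	30	16	940
CCND1	4	55	15	920
CREB1	5	70	14	900
KLF4	3	35	16	930
ZEB1	3	28	16	950
MYC	6	90	13	880
E2F1	4	60	15	910
NFKB1	4	48	15	925
FOXO1	3	33	16	935
GATA1	0	60	19	940
SP1	1	200	18	800
JUN	1	110	18	880
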