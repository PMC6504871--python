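# Published reference: the 18 steady-state attractors of the 19-protein
# migration network and the functional modules each facilitates.
# Bit order: PCM1 BBS4 CDK5 DIXC1 NDEL1 A4 LIS1 DAB1 CC141 MYH2 ZN365 GSK3B
#            DISC1 SOX10 FOXD3 RHEB ACTB AKT1 GRDN
row	bitstring	facilitated_fms
1	1111111111101000111	FM1,FM2,FM3,FM4,FM5,FM6,FM7,FM8
2	1111111111001000111	FM1,FM3,FM4,FM5,FM6,FM7,FM8
3	1111101011101000111	FM1,FM2,FM3,FM5,FM6,FM7,FM8
4	1111101011001000111	FM1,FM3,FM5,FM6,FM7,FM8
5	1100111111101000111	FM1,FM2,FM4,FM5,FM6,FM7,FM8
6	1100111111001000111	FM1,FM4,FM5,FM6,FM7,FM8
7	1100101011101000111	FM1,FM2,FM5,FM6,FM7,FM8
8	1100101011001000111	FM1,FM5,FM6,FM7,FM8
9	0011111111101000111	FM2,FM3,FM4,FM5,FM6,FM7,FM8
10	0011111111001000111	FM3,FM4,FM5,FM6,FM7,FM8
11	0011101011101000111	FM2,FM3,FM5,FM6,FM7,FM8
12	0010000000110111000	-
13	0010000000010111000	-
14	0000111111101000111	FM2,FM4,FM5,FM6,FM7,FM8
15	0000111111001000111	FM4,FM5,FM6,FM7,FM8
16	0000101011101000111	FM2,FM5,FM6,FM7,FM8
17	0000000000110111000	-
18	0000000000010111000	-
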