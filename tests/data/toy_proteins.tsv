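Protein ID	Gene	Combined Unique Peptides	S1 MaxLFQ Intensity	S2 MaxLFQ Intensity	S3 MaxLFQ Intensity	S4 MaxLFQ Intensity
P1	NIXL1	5	1024	2048	4096	8192
P2	WIPI2	8	300000		120000	250000
P3	SINGLE1	1	5500	0	6000	5800
contam_K1	KRT1	12	9e6	8e6	7e6	9.5e6
contam_K2	KRT2	4	100000		150000	90000
P4	BNIP3L	3	77000	81000	76000	80000
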