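receptor	uniprot_id	iptm	oligomeric_state
BNIP3	Q12983	0.66	monomer
NIX	O60238	0.65	monomer
FKBP8	Q14318	0.58	monomer
TEX264	Q9Y6I9	0.54	monomer
FAM134C	Q86VR2	0.46	monomer
CCPG1	Q9ULG6	0.2	monomer
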