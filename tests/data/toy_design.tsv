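sample_id	group	replicate
S1	GST	1
S2	GST	2
S3	bait	1
S4	bait	2
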