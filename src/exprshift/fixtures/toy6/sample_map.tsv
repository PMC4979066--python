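sample_id	species	tissue
S1_a1	S1	leaf
S1_a2	S1	leaf
S2	S2	leaf
S3	S3	leaf
S4	S4	leaf
S5	S5	leaf
S6	S6	leaf
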