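child	parent	bl_seq	bl_exp	rrbl
N2	N1	0.250573961109	0.50704791658	0.33852501231
N3	N1	0.580395648139	1.17445724559	0.33852501231
S1	N2	0.900256260959	0.645245422515	-0.165001980373
N4	N2	0.954446750847	0	-1
N5	N3	0.104560926012	0.025711868411	-0.605261121097
S2	N3	0.137118272005	0.0746695020302	-0.294864848828
S3	N5	0.326598527812	0	-1
S4	N5	0.10641714496	0.0995396466098	-0.0333929184731
S5	N4	0.0398496778544	0.480998166587	0.846981500337
S6	N4	0.0581602347165	0.450707636088	0.771413217248
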