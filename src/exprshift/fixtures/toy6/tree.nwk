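((S1:0.711293880773,(S5:0.103035045699,S6:0.103035045699)N4:0.608258835074)N2:0.288706119227,((S3:0.224629222216,S4:0.224629222216)N5:0.0461398158802,S2:0.270769038097)N3:0.729230961903)N1:0;
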