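((S1:0.900256260959,(S5:0.0398496778544,S6:0.0581602347165)N4:0.954446750847)N2:0.250573961109,((S3:0.326598527812,S4:0.10641714496)N5:0.104560926012,S2:0.137118272005)N3:0.580395648139)N1:0;
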