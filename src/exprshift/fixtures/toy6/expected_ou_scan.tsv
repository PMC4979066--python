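gene	best_node	loglik_ou1	loglik_ou2	lambda	p
g1	N2	1.84776873662	2.08845420435	0.481370935447	0.487801994591
g2	N2	-1.34768689897	3.31199797346	9.31936974486	0.0022674397363
g3	N2	1.94259637291	5.43655838389	6.98792402196	0.00820614783081
g4	N2	3.25911755681	3.59378257996	0.669330046309	0.413285280904
g5	none				
g6	N2	3.19300459546	3.44207782422	0.498146457504	0.480315686787
g7	N2	4.54784583309	4.83553820281	0.575384739439	0.448127063251
g8	N2	6.27721729392	8.46907327775	4.38371196766	0.0362838972686
g9	N2	-0.200414611389	3.10477913439	6.61038749156	0.010138559795
g10	N2	5.65657074954	6.51925203163	1.72536256419	0.189004226104
g11	N2	-0.513989573278	2.54824207498	6.12446329652	0.013332375773
g12	N2	1.44156736207	2.17676895788	1.47040319162	0.225282089926
g13	N2	0.00467699892318	4.27009202216	8.53083004647	0.00349180416257
g14	N2	0.570718095894	0.841459131434	0.541482071081	0.46181915639
g15	N2	1.902731174	6.64609792442	9.48673350082	0.00206962970468
g16	N2	11.9014817291	11.9052755746	0.00758769100703	0.93058618048
g17	N2	5.1577066089	7.89440864288	5.47340406796	0.0193079827405
g18	N2	2.09942872111	3.1822724462	2.16568745017	0.1411214997
g19	N2	-1.08799333332	1.91125913924	5.99850494513	0.0143180066681
g20	N2	4.45236160768	10.6094768742	12.3142305331	0.000449517980095
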