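gene_id	S1_a1	S1_a2	S2	S3	S4	S5	S6
g1	6.693438218576543	6.787047335865965	6.737574981162942	6.6185119172065034	6.577757853830597	7.028932218416769	6.460936250127555
g2	8.05000015058015	8.085153889903967	7.227034323415662	7.295566211449482	7.273365987819028	8.005781525970512	7.626592890060004
g3	9.512362023843274	9.53488106038877	9.995296005511008	9.909802595357489	9.86813184883733	9.81058030777468	9.559024421830896
g4	9.03801484868029	8.97251334863716	9.172911476835823	9.080602749316375	8.768377845693298	9.143821827788686	9.175687778908879
g5	8.343782321480468	8.335409096677077	8.38489089772226		8.002654133484853	8.326851914172526	8.020779054833925
g6	10.160935444008734	10.03284966717314	9.672524168129714	9.712492490668138	9.779736371368298	9.694909768619816	9.607449699837153
g7	7.415358810071654	7.48767922395431	7.3151463057403925	7.601127626840986	7.667037057546964	7.452492499888453	7.4663839929441185
g8	8.207374331764878	8.160759761988523	8.173347548092028	8.10652604986122	8.062145381129815	8.200411468676222	8.339593629808109
g9	4.798612419139078	4.847956693520221	5.477631909485728	5.479991312800235	5.620322778093416	5.292013809229169	5.008771343615279
g10	4.978960744579932	4.930746914130962	4.996424098783948	4.880206786320212	4.876332111338774	5.162342318660014	5.206872645061178
g11	6.986749462348467	7.078932358641105	7.351615779835644	7.770632121958583	7.683390981686807	6.724362505138753	6.7637706962314175
g12	5.821623606220519	5.768377584024473	5.322135689519334	5.11871956963204	5.237028469667848	5.230053458180984	5.3450214046405575
g13	7.842229817111674	7.8611696309349455	8.179697923734738	8.282742996206984	8.445754460003949	7.949436757038571	7.644076876408803
g14	11.164257424135542	11.013693283269712	11.754725641732195	11.638129824439138	11.596800188892058	11.84194058908619	11.69166921648406
g15	9.529826661639072	9.549255658813049	9.163052413695912	8.97756140527575	9.022440964697903	9.73775190817628	9.64711117441274
g16	8.063361883796702	8.146043377987176	8.169941150285938	8.169462967471954	8.108243290796059	8.189826668588376	8.184122872831187
g17	7.3375867629637765	7.2516936069666595	7.216660897527962	7.044535266745295	7.015188360004204	7.315981940843496	7.26009655095279
g18	9.301726368108234	9.14854548086197	8.605000483307482	8.53134859424294	8.693315664585759	8.766490663808131	8.74629446254874
g19	9.186119243274518	9.201412164681699	10.443323971612186	10.409998345935048	10.200134710130856	9.67214886947072	9.748748199362707
g20	12.47330968023318	12.511057219182902	12.211713453267727	12.227550665394837	12.23312928801288	12.597996815746592	12.464008836108004
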