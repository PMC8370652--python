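# synthetic CFU counts consistent with the printed fitness summaries
strain_id	reference_id	assay	replicate	t0_mutant	t0_reference	t1_mutant	t1_reference	dilution_t0	dilution_t1	generations
WspF_V271G	WspF_V271G	competition	1	99950	100050	100217	99783	1	1	10
WspF_V271G	WspF_V271G	competition	2	99902	100098	99818	100182	1	1	10
WspF_V271G	WspF_V271G	competition	3	100161	99839	99848	100152	1	1	10
WspF_V271G	WspF_V271G	competition	4	100102	99898	99751	100249	1	1	10
WspF_V271G	wild_type_GFP	invasion	1	1988	198012	39610	160390	1	1	10
WspF_V271G	wild_type_GFP	invasion	2	1996	198004	39397	160603	1	1	10
WspF_V271G	wild_type_GFP	invasion	3	2067	197933	39520	160480	1	1	10
WspF_V271G	wild_type_GFP	invasion	4	1984	198016	39631	160369	1	1	10
WspF_V271G	wild_type_GFP	invasion	5	1945	198055	39292	160708	1	1	10
WspF_V271G	wild_type_GFP	invasion	6	1942	198058	39568	160432	1	1	10
WspE_S575F	WspF_V271G	competition	1	99998	100002	110322	89678	1	1	10
WspE_S575F	WspF_V271G	competition	2	99744	100256	110084	89916	1	1	10
WspE_S575F	WspF_V271G	competition	3	100013	99987	110113	89887	1	1	10
WspE_S575F	WspF_V271G	competition	4	100390	99610	109953	90047	1	1	10
WspE_S575F	wild_type_GFP	invasion	1	1960	198040	42551	157449	1	1	10
WspE_S575F	wild_type_GFP	invasion	2	2008	197992	42520	157480	1	1	10
WspE_S575F	wild_type_GFP	invasion	3	1974	198026	42846	157154	1	1	10
WspE_S575F	wild_type_GFP	invasion	4	1943	198057	42999	157001	1	1	10
WspE_S575F	wild_type_GFP	invasion	5	1967	198033	42602	157398	1	1	10
WspE_S575F	wild_type_GFP	invasion	6	1981	198019	42644	157356	1	1	10
MwsR_A980T	WspF_V271G	competition	1	99906	100094	105195	94805	1	1	10
MwsR_A980T	WspF_V271G	competition	2	100290	99710	104981	95019	1	1	10
MwsR_A980T	WspF_V271G	competition	3	100186	99814	105044	94956	1	1	10
MwsR_A980T	WspF_V271G	competition	4	100182	99818	105329	94671	1	1	10
MwsR_A980T	wild_type_GFP	invasion	1	1978	198022	36298	163702	1	1	10
MwsR_A980T	wild_type_GFP	invasion	2	2043	197957	36297	163703	1	1	10
MwsR_A980T	wild_type_GFP	invasion	3	1926	198074	36337	163663	1	1	10
MwsR_A980T	wild_type_GFP	invasion	4	1914	198086	36132	163868	1	1	10
MwsR_A980T	wild_type_GFP	invasion	5	1964	198036	36224	163776	1	1	10
MwsR_A980T	wild_type_GFP	invasion	6	1988	198012	36235	163765	1	1	10
AwsX_L60P	WspF_V271G	competition	1	100145	99855	85314	114686	1	1	10
AwsX_L60P	WspF_V271G	competition	2	100217	99783	84963	115037	1	1	10
AwsX_L60P	WspF_V271G	competition	3	100537	99463	85037	114963	1	1	10
AwsX_L60P	WspF_V271G	competition	4	100751	99249	85016	114984	1	1	10
AwsX_L60P	wild_type_GFP	invasion	1	1966	198034	33543	166457	1	1	10
AwsX_L60P	wild_type_GFP	invasion	2	1963	198037	33507	166493	1	1	10
AwsX_L60P	wild_type_GFP	invasion	3	2049	197951	33565	166435	1	1	10
AwsX_L60P	wild_type_GFP	invasion	4	2013	197987	33320	166680	1	1	10
AwsX_L60P	wild_type_GFP	invasion	5	2008	197992	33172	166828	1	1	10
AwsX_L60P	wild_type_GFP	invasion	6	1991	198009	33448	166552	1	1	10
AwsR_T27I	WspF_V271G	competition	1	99997	100003	90067	109933	1	1	10
AwsR_T27I	WspF_V271G	competition	2	100055	99945	90088	109912	1	1	10
AwsR_T27I	WspF_V271G	competition	3	99722	100278	90083	109917	1	1	10
AwsR_T27I	WspF_V271G	competition	4	100480	99520	90014	109986	1	1	10
AwsR_T27I	wild_type_GFP	invasion	1	1948	198052	30788	169212	1	1	10
AwsR_T27I	wild_type_GFP	invasion	2	1995	198005	30795	169205	1	1	10
AwsR_T27I	wild_type_GFP	invasion	3	1961	198039	30732	169268	1	1	10
AwsR_T27I	wild_type_GFP	invasion	4	2014	197986	30962	169038	1	1	10
AwsR_T27I	wild_type_GFP	invasion	5	1979	198021	30728	169272	1	1	10
AwsR_T27I	wild_type_GFP	invasion	6	1976	198024	30394	169606	1	1	10
WspA_T293del	WspF_V271G	competition	1	99523	100477	75402	124598	1	1	10
WspA_T293del	WspF_V271G	competition	2	100258	99742	75292	124708	1	1	10
WspA_T293del	WspF_V271G	competition	3	100011	99989	75354	124646	1	1	10
WspA_T293del	WspF_V271G	competition	4	100093	99907	75375	124625	1	1	10
WspA_T293del	wild_type_GFP	invasion	1	2031	197969	21935	178065	1	1	10
WspA_T293del	wild_type_GFP	invasion	2	1975	198025	21715	178285	1	1	10
WspA_T293del	wild_type_GFP	invasion	3	1957	198043	21507	178493	1	1	10
WspA_T293del	wild_type_GFP	invasion	4	2035	197965	21901	178099	1	1	10
WspA_T293del	wild_type_GFP	invasion	5	2039	197961	21790	178210	1	1	10
WspA_T293del	wild_type_GFP	invasion	6	1966	198034	21616	178384	1	1	10
PFL_0087_D230G	WspF_V271G	competition	1	100006	99994	71002	128998	1	1	10
PFL_0087_D230G	WspF_V271G	competition	2	100101	99899	70990	129010	1	1	10
PFL_0087_D230G	WspF_V271G	competition	3	100072	99928	71434	128566	1	1	10
PFL_0087_D230G	WspF_V271G	competition	4	100040	99960	70879	129121	1	1	10
PFL_0087_D230G	wild_type_GFP	invasion	1	1943	198057	19944	180056	1	1	10
PFL_0087_D230G	wild_type_GFP	invasion	2	1938	198062	19660	180340	1	1	10
PFL_0087_D230G	wild_type_GFP	invasion	3	1976	198024	19675	180325	1	1	10
PFL_0087_D230G	wild_type_GFP	invasion	4	1975	198025	20004	179996	1	1	10
PFL_0087_D230G	wild_type_GFP	invasion	5	2014	197986	19772	180228	1	1	10
PFL_0087_D230G	wild_type_GFP	invasion	6	1944	198056	19694	180306	1	1	10
PFL_3078_promoter	WspF_V271G	competition	1	100059	99941	53915	146085	1	1	10
PFL_3078_promoter	WspF_V271G	competition	2	99953	100047	54037	145963	1	1	10
PFL_3078_promoter	WspF_V271G	competition	3	99863	100137	53813	146187	1	1	10
PFL_3078_promoter	WspF_V271G	competition	4	99804	100196	53696	146304	1	1	10
PFL_3078_promoter	wild_type_GFP	invasion	1	2005	197995	13909	186091	1	1	10
PFL_3078_promoter	wild_type_GFP	invasion	2	1974	198026	13587	186413	1	1	10
PFL_3078_promoter	wild_type_GFP	invasion	3	1982	198018	13650	186350	1	1	10
PFL_3078_promoter	wild_type_GFP	invasion	4	1949	198051	13775	186225	1	1	10
PFL_3078_promoter	wild_type_GFP	invasion	5	1959	198041	13698	186302	1	1	10
PFL_3078_promoter	wild_type_GFP	invasion	6	1892	198108	13591	186409	1	1	10
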