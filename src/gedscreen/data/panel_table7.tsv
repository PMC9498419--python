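SNV_ID	Chromosome	Location	REF_allele	ALT_allele	REF_frequency	He	PE1	PE2
BIEC2-11336	1	24061861	C	T	0.582	0.487	0.184	0.118
BIEC2-23891	1	58467370	T	C	0.847	0.259	0.113	0.034
BIEC2-34560	1	80153039	T	C	0.520	0.499	0.187	0.125
BIEC2-34987	1	81012651	T	G	0.724	0.399	0.160	0.080
BIEC42118	1	102064366	C	T	0.255	0.380	0.154	0.072
BIEC2-60186	1	138352227	A	C	0.755	0.370	0.151	0.068
BIEC2-65145	1	153834277	C	T	0.635	0.463	0.178	0.107
BIEC2-78523	1	166558525	G	A	0.592	0.483	0.183	0.117
BIEC2-459311	2	17808463	T	C	0.740	0.385	0.156	0.074
BIEC2-476920	2	46942336	C	A	0.633	0.465	0.178	0.108
BIEC2-491394	2	78433836	A	G	0.571	0.490	0.185	0.120
BIEC2-502451	2	98905614	A	G	0.673	0.440	0.172	0.097
BIEC420894	2	120778620	T	C	0.653	0.453	0.175	0.103
BIEC2-777914	3	38956274	T	C	0.622	0.470	0.180	0.110
BIEC672139	3	86457199	T	C	0.694	0.425	0.167	0.090
BIEC2-798927	3	88082655	A	G	0.633	0.465	0.178	0.108
BIEC2-799664	3	90095202	C	A	0.646	0.457	0.176	0.105
BIEC2-800511	3	91766696	T	C	0.235	0.359	0.147	0.065
BIEC2-806771	3	101540587	G	A	0.816	0.300	0.127	0.045
BIEC681989	3	104518656	C	T	0.592	0.483	0.183	0.117
BIEC2-811886	3	119599447	G	A	0.327	0.440	0.172	0.097
BIEC707898	4	178566	T	C	0.729	0.395	0.158	0.078
BIEC2-853347	4	21336785	G	A	0.602	0.479	0.182	0.115
BIEC2-908630	5	45880924	C	T	0.531	0.498	0.187	0.124
BIEC2-910827	5	53722932	T	G	0.604	0.478	0.182	0.114
BIEC2-914714	5	63272427	T	C	0.378	0.470	0.180	0.110
BIEC2-919835	5	73509875	G	T	0.724	0.399	0.160	0.080
BIEC2-946446	6	32343233	A	G	0.704	0.417	0.165	0.087
BIEC798010	6	45478480	A	G	0.398	0.479	0.182	0.115
BIEC811791	6	76708313	G	T	0.622	0.470	0.180	0.110
BIEC819385	7	5215592	A	C	0.480	0.499	0.187	0.125
BIEC2-1007607	7	80202186	C	T	0.520	0.499	0.187	0.125
BIEC870244	8	17383321	G	C	0.653	0.453	0.175	0.103
BIEC871916	8	20028234	A	T	0.551	0.495	0.186	0.122
BIEC2-1052417	8	57040628	C	T	0.714	0.408	0.162	0.083
BIEC2-1066033	8	94179121	G	T	0.520	0.499	0.187	0.125
BIEC2-1066179	8	95184881	G	A	0.735	0.390	0.157	0.076
BIEC2-1080866	9	25656223	T	C	0.551	0.495	0.186	0.122
BIEC915102	9	27114849	C	T	0.500	0.500	0.188	0.125
BIEC86281	10	922571	C	T	0.439	0.493	0.186	0.121
BIEC2-95522	10	4751573	A	G	0.531	0.498	0.187	0.124
BIEC2-97679	10	7701310	G	A	0.643	0.459	0.177	0.105
BIEC2-119640	10	44453287	T	C	0.673	0.440	0.172	0.097
BIEC2-121102	10	48342330	A	G	0.735	0.390	0.157	0.076
BIEC2-123002	10	52573273	T	C	0.867	0.230	0.102	0.026
BIEC2-126732	10	60049178	A	G	0.408	0.483	0.183	0.117
BIEC119158	10	65321527	A	T	0.582	0.487	0.184	0.118
BIEC2-136591	11	7641341	T	C	0.510	0.500	0.187	0.125
BIEC136821	11	29398313	A	G	0.592	0.483	0.183	0.117
BIEC2-162245	11	57232386	C	T	0.653	0.453	0.175	0.103
BIEC154171	12	3878382	G	T	0.337	0.447	0.173	0.100
BIEC155175	12	5186277	C	T	0.698	0.422	0.166	0.089
BIEC2-189666	12	22012560	G	A	0.551	0.495	0.186	0.122
BIEC2-214346	13	19184556	G	A	0.490	0.500	0.187	0.125
BIEC180122	13	35676903	A	G	0.663	0.447	0.173	0.100
BIEC183067	14	4666366	A	G	0.520	0.499	0.187	0.125
BIEC2-245923	14	14775426	C	T	0.704	0.417	0.165	0.087
BIEC204022	14	64551633	A	G	0.813	0.305	0.129	0.046
BIEC2-263616	14	69988182	C	A	0.480	0.499	0.187	0.125
BIEC2-270795	14	83088387	C	T	0.418	0.487	0.184	0.118
BIEC2-278532	15	1201270	A	G	0.776	0.348	0.144	0.061
BIEC247284	15	48661214	G	A	0.633	0.465	0.178	0.108
BIEC2-310269	15	52664101	T	C	0.406	0.482	0.183	0.116
BIEC2-326637	16	1496069	A	G	0.622	0.470	0.180	0.110
BIEC266761	16	3860430	C	T	0.571	0.490	0.185	0.120
BIEC2-328954	16	8598011	A	G	0.398	0.479	0.182	0.115
BIEC2-336269	16	27983909	G	A	0.235	0.359	0.147	0.065
BIEC2-340595	16	36915439	A	G	0.408	0.483	0.183	0.117
BIEC2-342881	16	42323485	C	T	0.602	0.479	0.182	0.115
BIEC2-358061	16	71914513	C	T	0.296	0.417	0.165	0.087
BIEC2-364741	16	83054140	G	A	0.684	0.433	0.169	0.094
BIEC2-364945	16	84257390	C	T	0.541	0.497	0.187	0.123
BIEC2-369699	17	17649634	G	A	0.510	0.500	0.187	0.125
BIEC2-374571	17	27036258	A	G	0.653	0.453	0.175	0.103
BIEC322734	17	78660174	A	G	0.480	0.499	0.187	0.125
BIEC2-390920	18	2190684	A	C	0.745	0.380	0.154	0.072
BIEC324530	18	11431365	C	T	0.633	0.465	0.178	0.108
BIEC2-407206	18	17621415	A	G	0.429	0.490	0.185	0.120
BIEC2-415315	18	56944269	G	A	0.510	0.500	0.187	0.125
BIEC2-430577	19	19611080	A	G	0.296	0.417	0.165	0.087
BIEC2-439060	19	42595105	C	T	0.688	0.430	0.169	0.092
BIEC2-442892	19	48488636	T	C	0.622	0.470	0.180	0.110
BIEC431445	20	16383556	T	C	0.281	0.404	0.161	0.082
BIEC2-530788	20	33600979	T	C	0.480	0.499	0.187	0.125
BIEC2-532106	20	40481673	C	T	0.571	0.490	0.185	0.120
BIEC2-535766	20	49037728	T	C	0.551	0.495	0.186	0.122
BIEC2-575436	22	2011040	C	T	0.582	0.487	0.184	0.118
BIEC2-584911	22	19064667	A	G	0.398	0.479	0.182	0.115
BIEC493879	22	30797481	C	T	0.296	0.417	0.165	0.087
BIEC499860	22	40978756	T	G	0.551	0.495	0.186	0.122
BIEC2-606469	23	4277770	G	A	0.612	0.475	0.181	0.113
BIEC508410	23	16413178	C	G	0.542	0.497	0.187	0.123
BIEC2-618284	23	19540553	G	T	0.750	0.375	0.152	0.070
BIEC523483	24	12615461	T	C	0.229	0.353	0.145	0.062
BIEC2-636987	24	17444264	C	T	0.694	0.425	0.167	0.090
BIEC531275	24	27556162	C	T	0.296	0.417	0.165	0.087
BIEC532060	24	28656489	A	G	0.612	0.475	0.181	0.113
BIEC541693	24	45741983	C	T	0.694	0.425	0.167	0.090
BIEC555737	25	12340280	G	A	0.635	0.463	0.178	0.107
BIEC554813	25	14083078	C	G	0.347	0.453	0.175	0.103
BIEC581695	26	1937434	G	A	0.469	0.498	0.187	0.124
BIEC571705	26	19267701	T	C	0.561	0.493	0.186	0.121
BIEC2-692543	26	30370457	G	A	0.684	0.433	0.169	0.094
BIEC562465	26	42126216	A	G	0.265	0.390	0.157	0.076
BIEC2-708018	27	18560786	C	T	0.724	0.399	0.160	0.080
BIEC590986	27	19761701	T	A	0.663	0.447	0.173	0.100
BIEC2-721061	27	38093323	T	C	0.367	0.465	0.178	0.108
BIEC604433	27	39476969	G	T	0.173	0.287	0.123	0.041
BIEC2-725322	28	5600796	C	T	0.604	0.478	0.182	0.114
BIEC607490	28	5913256	G	T	0.500	0.500	0.188	0.125
BIEC2-734103	28	21956151	C	T	0.439	0.493	0.186	0.121
BIEC617070	28	23842936	T	C	0.704	0.417	0.165	0.087
BIEC2-737704	28	30865784	G	T	0.418	0.487	0.184	0.118
BIEC633181	29	13672303	G	C	0.327	0.440	0.172	0.097
BIEC633979	29	15765096	T	C	0.357	0.459	0.177	0.105
BIEC2-761851	29	29285909	T	G	0.867	0.230	0.102	0.026
BIEC2-816793	30	7757606	T	G	0.531	0.498	0.187	0.124
BIEC686800	30	12032090	T	G	0.153	0.259	0.113	0.034
BIEC696480	31	1930525	T	C	0.490	0.500	0.187	0.125
BIEC2-838630	31	16325150	C	T	0.571	0.490	0.185	0.120
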