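gene	mean	variance	var_std
g000	 1.77	  7.75464646465	2.1101502770
g001	 1.04	  1.93777777778	1.2561865899
g002	 0.75	  1.50252525253	1.3605760803
g003	 3.64	 20.89939393939	1.6676844214
g004	 0.39	  0.46252525253	1.0184865176
g005	 2.80	 10.86868686869	1.4339234774
g006	 4.17	 31.19303030303	1.9818222043
g007	 1.03	  1.28191919192	0.8397862342
g008	 0.20	  0.24242424242	1.1780458635
g009	21.71	586.26858585859	1.0548245853
g010	 0.47	  0.59505050505	1.0636030214
g011	 0.56	  0.59232323232	0.8933432854
g012	 4.14	 15.27313131313	0.9811133454
g013	 2.14	  5.15191919192	1.0637103485
g014	 0.12	  0.12686868687	0.9861029371
g015	 1.21	  1.78373737374	0.9275940823
g016	 1.60	  2.88888888889	0.9238538223
g017	 0.71	  0.77363636364	0.7710724228
g018	 0.06	  0.07717171717	1.1195748844
g019	 0.07	  0.08595959596	1.0841819596
g020	 1.85	  3.66414141414	0.9348933426
g021	 0.76	  1.41656565657	1.2520161929
g022	 0.26	  0.23474747475	0.8604081736
g023	 3.54	 11.24080808081	0.9441514403
g024	 1.56	  2.95595959596	0.9865763514
g025	 0.89	  1.27060606061	0.9023716232
g026	 0.56	  0.59232323232	0.8933432854
g027	 3.36	  9.44484848485	0.8755897497
g028	 1.21	  1.96555555556	1.0221446995
g029	 2.06	  3.63272727273	0.7926875141
g030	 0.54	  0.69535353535	1.0897249912
g031	 0.29	  0.28878787879	0.9334678487
g032	 3.60	  8.86868686869	0.7221210792
g033	 1.15	  1.80555555556	1.0134752428
g034	 0.10	  0.11111111111	1.0147516073
g035	 0.27	  0.27989898990	0.9828476817
g036	 0.46	  0.63474747475	1.1625523238
g037	 0.24	  0.18424242424	0.7396218851
g038	 0.34	  0.36808080808	0.9663374449
g039	 0.58	  0.65010101010	0.9359614175
g040	 4.27	 13.65363636364	0.8364411616
g041	 2.17	  5.11222222222	1.0341906224
g042	 1.70	  3.16161616162	0.9133024000
g043	 4.68	 18.32080808081	0.9709834648
g044	 1.81	  4.39787878788	1.1586469431
g045	 0.31	  0.51909090909	1.5430696986
g046	 0.41	  0.46656565657	0.9701239572
g047	 7.74	 34.17414141414	0.7306197412
g048	 1.16	  1.57010101010	0.8710156609
g049	 1.49	  2.73727272727	0.9912657368
g050	 0.44	  0.53171717172	1.0227633799
g051	 1.07	  1.74252525253	1.0887857000
g052	 0.98	  1.47434343434	0.9909429070
g053	 2.49	  5.22212121212	0.8520039917
g054	 0.17	  0.16272727273	0.9240687367
g055	 0.77	  0.92636363636	0.8016083330
g056	 1.21	  1.66252525253	0.8645603376
g057	 0.15	  0.14898989899	0.9500125224
g058	 1.24	  2.12363636364	1.0610432799
g059	 0.65	  0.83585858586	0.9869257838
g060	 0.06	  0.05696969697	0.8264924539
g061	 0.44	  0.53171717172	1.0227633799
g062	 0.83	  1.39505050505	1.0744762445
g063	 0.75	  1.03787878788	0.9398265025
g064	 0.89	  1.69484848485	1.2036643187
g065	 1.25	  2.97727272727	1.4690646633
g066	 1.03	  1.46373737374	0.9588954629
g067	 0.79	  0.93525252525	0.7766199684
g068	 1.39	  2.30090909091	0.9468424364
g069	 1.69	  3.16555555556	0.9228844196
g070	 0.96	  1.35191919192	0.9216964230
g071	 0.40	  0.40404040404	0.8641321299
g072	 0.50	  0.73737373737	1.2357417761
g073	 1.36	  1.84888888889	0.7915969414
g074	 1.04	  1.19030303030	0.7716275425
g075	 0.45	  0.65404040404	1.2277200125
g076	 0.48	  0.51474747475	0.8984423356
g077	 0.25	  0.33080808081	1.2680188829
g078	 0.47	  0.67585858586	1.2080407089
g079	 1.15	  1.98737373737	1.1155314910
g080	 0.83	  1.07181818182	0.8255207755
g081	 0.23	  0.23949494949	1.0073784997
g082	 1.85	  2.85606060606	0.7287142457
g083	 0.87	  1.85161616162	1.3411508292
g084	 1.66	  2.63070707071	0.7898435636
g085	 0.52	  0.47434343434	0.7685999903
g086	 0.12	  0.14707070707	1.1431256978
g087	 0.29	  0.26858585859	0.8681675445
g088	 0.47	  0.43343434343	0.7747276464
g089	 2.56	  5.31959595960	0.8273530688
g090	 0.24	  0.24484848485	0.9829185578
g091	 1.21	  2.08676767677	1.0851784442
g092	 0.43	  0.38898989899	0.7669955566
g093	 1.40	  2.18181818182	0.8861062767
g094	 0.52	  0.81777777778	1.3250820957
g095	 0.42	  0.48848484848	0.9885252756
g096	 4.60	 13.59595959596	0.7408287658
g097	 1.59	  4.08272727273	1.3194246649
g098	 0.96	  1.65494949495	1.1282930510
g099	 0.76	  1.23474747475	1.0913181647
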