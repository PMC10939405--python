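# Published grapevine marker-trait association table (69 significant SNP hits).
# Transcribed from the printed results table of the source study; coordinates are
# 1-based bp on the PN40024.12X assembly. region_ini/region_fin is the +/-25 kbp
# search window as printed (the chr11 S_fresh row prints a +/-50 kbp window and no
# candidate gene). distance is SNP-to-nearest-gene-boundary in bp, 0 = SNP inside gene.
trait	chrom	position	snp	lod	region_ini	region_fin	gene_ini	gene_fin	gene	distance
S_fresh	chr01	22306525	M_01_22306525	5.37	22281525	22331525	22304288	22306564	Vitvi01g02270	0
S_fresh	chr02	6686801	M_02_6686801	6.9	6661801	6711801	6682700	6682873	Vitvi02g01487	3928
S_fresh	chr09	7065439	M_09_7065439	4.93	7040439	7090439	7066313	7072358	Vitvi09g00629	874
S_fresh	chr11	13989722	M_11_13989722	14.68	13939722	14039722	NA	NA	NA	NA
S_fresh	chr13	8151231	M_13_8151231	5.29	8126231	8176231	8148964	8153524	Vitvi13g00739	0
S_fresh	chr14	6659734	M_14_6659734	6.84	6634734	6684734	6654655	6665536	Vitvi14g00427	0
S_fresh	chr14	7345807	M_14_7345807	6.64	7320807	7370807	7337163	7389121	Vitvi14g00472	0
S_fresh	chr15	16996087	M_15_16996087	5.07	16971087	17021087	16991674	16996074	Vitvi15g00913	13
S_fresh	chr18	19681084	M_18_19681084	6.89	19656084	19706084	19682424	19685819	Vitvi18g01490	1340
S_fresh	chr18	26994029	M_18_26994029	5.59	26969029	27019029	26991171	26994231	Vitvi18g03065	0
S_fresh	chr18	27016113	M_18_27016113	7.77	26991113	27041113	27018029	27018546	Vitvi18g01900	1916
S_fresh	chr19	3265960	M_19_3265960	6.84	3240960	3290960	3265452	3267338	Vitvi19g00252	0
S_fresh	chr19	5737748	M_19_5737748	5.77	5712748	5762748	5736473	5737761	Vitvi19g00425	0
S_fresh	chr19	7843732	M_19_7843732	6.91	7818732	7868732	7842956	7844371	Vitvi19g00626	0
S_dry	chr01	19586589	M_01_19586589	6.09	19561589	19611589	19584338	19585799	Vitvi01g01459	790
S_dry	chr04	19371161	M_04_19371161	5.86	19346161	19396161	19354505	19373873	Vitvi04g01364	0
S_dry	chr18	26395984	M_18_26395984	12.61	26370984	26420984	26391565	26392582	Vitvi18g01868	3402
S_dry	chr18	26585996	M_18_26585996	6.16	26560996	26610996	26580060	26581774	Vitvi18g01875	4222
S_dry	chr18	27016067	M_18_27016067	14.96	26991067	27041067	27018029	27018546	Vitvi18g01900	1962
S_dry	chr18	27641922	M_18_27641922	7.93	27616922	27666922	27645019	27647663	Vitvi18g01937	3097
S_dry	chr19	5737748	M_19_5737748	5.66	5712748	5762748	5736473	5737761	Vitvi19g00425	0
B_height	chr03	3308146	M_03_3308146	5.62	3283146	3333146	3308692	3320395	Vitvi03g00299	546
B_height	chr05	986588	M_05_986588	7.48	961588	1011588	984657	1007813	Vitvi05g00106	0
B_height	chr05	2487910	M_05_2487910	13.15	2462910	2512910	2487510	2488673	Vitvi05g00235	0
B_height	chr08	11609006	M_08_11609006	6.88	11584006	11634006	11608451	11609203	Vitvi08g00929	0
B_height	chr08	20838429	M_08_20838429	5.34	20813429	20863429	20837623	20841031	Vitvi08g01794	0
B_height	chr11	2440870	M_11_2440870	5.69	2415870	2465870	2439052	2442344	Vitvi11g00257	0
B_height	chr14	28926364	M_14_28926364	6.59	28901364	28951364	28923196	28926504	Vitvi14g01907	0
B_width	chr02	2926867	M_02_2926867	7.63	2901867	2951867	2886776	2931532	Vitvi02g00329	0
B_width	chr05	872428	M_05_872428	5.99	847428	897428	868859	873471	Vitvi05g00090	0
B_width	chr06	4874960	M_06_4874960	7.67	4849960	4899960	4874372	4880988	Vitvi06g00389	0
B_width	chr07	4139218	M_07_4139218	7.39	4114218	4164218	4132329	4139353	Vitvi07g00394	0
B_width	chr08	17678111	M_08_17678111	8.22	17653111	17703111	17676410	17678357	Vitvi08g01496	0
B_width	chr08	20850513	M_08_20850513	7.12	20825513	20875513	20848483	20853959	Vitvi08g02367	0
B_width	chr11	4447151	M_11_4447151	19.1	4422151	4472151	4444763	4448289	Vitvi11g00454	0
B_width	chr17	6092969	M_17_6092969	6.32	6067969	6117969	6090734	6093282	Vitvi17g00518	0
B_width	chr18	7568138	M_18_7568138	6.66	7543138	7593138	7566258	7569958	Vitvi18g00659	0
B_width	chr18	25163895	M_18_25163895	5.49	25138895	25188895	25162572	25162781	Vitvi18g01775	1114
B_width	chr18	26686497	M_18_26686497	6.33	26661497	26711497	26686202	26689010	Vitvi18g01881	0
B_shape	chr01	9976460	M_01_9976460	6.72	9951460	10001460	9958225	10030522	Vitvi01g00836	0
B_shape	chr04	14862225	M_04_14862225	6.33	14837225	14887225	14859361	14871185	Vitvi04g01015	0
B_shape	chr05	336776	M_05_336776	5.9	311776	361776	331674	336883	Vitvi05g00035	0
B_shape	chr08	10520542	M_08_10520542	6.18	10495542	10545542	10519601	10523796	Vitvi08g00843	0
B_shape	chr09	16162993	M_09_16162993	6.75	16137993	16187993	16161179	16164595	Vitvi09g01126	0
B_shape	chr10	16424430	M_10_16424430	5.14	16399430	16449430	16426963	16432120	Vitvi10g01968	2533
B_shape	chr14	2453773	M_14_2453773	9.12	2428773	2478773	2452756	2461383	Vitvi14g00215	0
B_shape	chr16	16819874	M_16_16819874	11.59	16794874	16844874	16818864	16822044	Vitvi16g01838	0
B_shape	chr18	12709493	M_18_12709493	5.98	12684493	12734493	12710589	12716432	Vitvi18g01148	1096
B_weight	chr15	485443	M_15_485443	7.72	460443	510443	465016	502021	Vitvi15g00014	0
H_cluster	chr02	351130	M_02_351130	5.24	326130	376130	349796	356484	Vitvi02g00042	0
H_cluster	chr04	20111668	M_04_20111668	7.14	20086668	20136668	20109346	20112709	Vitvi04g01437	0
H_cluster	chr08	18000198	M_08_18000198	5.67	17975198	18025198	17999555	18004028	Vitvi08g01523	0
H_cluster	chr08	21589248	M_08_21589248	7.48	21564248	21614248	21586857	21590446	Vitvi08g01881	0
H_cluster	chr11	2000210	M_11_2000210	5.1	1975210	2025210	1998468	2000661	Vitvi11g00204	0
H_cluster	chr17	489172	M_17_489172	5.51	464172	514172	491337	493421	Vitvi17g00052	2165
H_cluster	chr18	19715793	M_18_19715793	5.99	19690793	19740793	19724351	19725457	Vitvi18g01493	8558
H_rachis	chr12	5570431	M_12_5570431	6.71	5545431	5595431	5568686	5571047	Vitvi12g00381	0
H_rachis	chr16	1985967	M_16_1985967	7.13	1960967	2010967	1984817	1986052	Vitvi16g00127	0
P_cluster	chr18	949485	M_18_949485	7.75	924485	974485	949048	961392	Vitvi18g00099	0
P_cluster	chr18	25170861	M_18_25170861	14.53	25145861	25195861	25162572	25162781	Vitvi18g01775	8080
P_cluster_loss	chr02	3949944	M_02_3949944	6.87	3924944	3974944	3943909	3950772	Vitvi02g00420	0
P_cluster_loss	chr11	7552711	M_11_7552711	7.92	7527711	7577711	7548641	7554321	Vitvi11g00663	0
P_cluster_loss	chr18	27103699	M_18_27103699	11.59	27078699	27128699	27090552	27102800	Vitvi18g03067	899
P_rachis	chr02	2666566	M_02_2666566	11.38	2641566	2691566	2666209	2683214	Vitvi02g00307	0
P_rachis	chr04	17435135	M_04_17435135	9.96	17410135	17460135	17437440	17445220	Vitvi04g01187	2305
P_rachis	chr09	7543821	M_09_7543821	6.72	7518821	7568821	7531387	7545793	Vitvi09g00653	0
P_rachis	chr15	12041437	M_15_12041437	7.75	12016437	12066437	12041338	12042616	Vitvi15g00557	0
P_rachis	chr18	26395984	M_18_26395984	8.73	26370984	26420984	26391565	26392582	Vitvi18g01868	3402
P_rachis	chr19	10748969	M_19_10748969	6.69	10723969	10773969	10747971	10749212	Vitvi19g00932	0
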