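sample_id	dataset_id	age_days
GSM3466957	GSE122470	3
GSM3466958	GSE122470	3
GSM3466959	GSE122470	3
GSM3466960	GSE122470	15
GSM3466961	GSE122470	15
GSM3466962	GSE122470	15
GSM3466963	GSE122470	30
GSM3466964	GSE122470	30
GSM3466965	GSE122470	30
GSM3466966	GSE122470	45
GSM3466967	GSE122470	45
GSM3466968	GSE122470	45
GSM1945845	GSE75216	7
GSM1945846	GSE75216	7
GSM1945847	GSE75216	7
GSM1945855	GSE75216	7
GSM1945856	GSE75216	7
GSM1945843	GSE75216	22
GSM1945844	GSE75216	22
GSM1945853	GSE75216	22
GSM1945854	GSE75216	22
GSM1564407	GSE64108	21
GSM1564408	GSE64108	21
GSM1564409	GSE64108	21
GSM1564410	GSE64108	21
GSM1564415	GSE64108	35
GSM1564417	GSE64108	35
GSM1564419	GSE64108	35
GSM1564421	GSE64108	35
GSM1564431	GSE64108	49
GSM1564432	GSE64108	49
GSM1564433	GSE64108	49
GSM1564434	GSE64108	49
GSM1186462	GSE38998	3
GSM1186463	GSE38998	3
GSM953478	GSE38998	10
GSM953479	GSE38998	10
GSM2143625	GSE81100	5
GSM2143626	GSE81100	5
GSM2143627	GSE81100	5
GSM2143628	GSE81100	5
GSM2143629	GSE81100	5
GSM2143630	GSE81100	5
GSM2143631	GSE81100	5
GSM2143632	GSE81100	5
GSM2143633	GSE81100	5
GSM2143634	GSE81100	5
GSM2143635	GSE81100	5
GSM2143636	GSE81100	5
GSM2143637	GSE81100	55
GSM2143638	GSE81100	55
GSM2143639	GSE81100	55
GSM2143640	GSE81100	55
GSM2143641	GSE81100	55
GSM2143642	GSE81100	55
GSM2143643	GSE81100	55
GSM2143644	GSE81100	55
GSM2143645	GSE81100	55
GSM2143646	GSE81100	55
GSM2143647	GSE81100	55
GSM2143648	GSE81100	55
GSM2978238	GSE110135	3
GSM2978239	GSE110135	3
GSM2978240	GSE110135	3
GSM2978241	GSE110135	20
GSM2978242	GSE110135	20
GSM2978243	GSE110135	20
GSM12770	GSE6430	3
GSM12772	GSE6430	47
GSM2570129	GSE97493	3
GSM2570130	GSE97493	3
GSM2570131	GSE97493	3
GSM2570132	GSE97493	3
GSM2570133	GSE97493	3
GSM2570134	GSE97493	10
GSM2570135	GSE97493	10
GSM2570136	GSE97493	10
GSM2570137	GSE97493	10
GSM2570138	GSE97493	10
GSM2570159	GSE97493	10
GSM2570160	GSE97493	10
GSM2570161	GSE97493	10
GSM2570162	GSE97493	10
GSM2570163	GSE97493	10
GSM2570164	GSE97493	10
GSM2570149	GSE97493	30
GSM2570150	GSE97493	30
GSM2570151	GSE97493	30
GSM2570152	GSE97493	30
GSM2570153	GSE97493	30
GSM2570154	GSE97493	45
GSM2570155	GSE97493	45
GSM2570156	GSE97493	45
GSM2570157	GSE97493	45
GSM2570158	GSE97493	45
GSM2599109	GSE98554	2
GSM2599110	GSE98554	2
GSM2599111	GSE98554	2
GSM2599112	GSE98554	25
GSM2599113	GSE98554	25
GSM2599114	GSE98554	25
GSM1183416	GSE48681	3
GSM1183417	GSE48681	3
GSM1183418	GSE48681	3
GSM1183419	GSE48681	3
GSM1183420	GSE48681	10
GSM1183421	GSE48681	10
GSM1183422	GSE48681	10
GSM1183423	GSE48681	10
GSM1183424	GSE48681	20
GSM1183425	GSE48681	20
GSM1183426	GSE48681	20
GSM1183427	GSE48681	56
GSM1183428	GSE48681	56
GSM1183429	GSE48681	56
GSM1183430	GSE48681	56
GSM1183435	GSE48681	68
GSM1183436	GSE48681	68
GSM1183437	GSE48681	68
GSM1183438	GSE48681	68
GSM614349	GSE25009	3
GSM614350	GSE25009	3
GSM614351	GSE25009	3
GSM614352	GSE25009	30
GSM614353	GSE25009	30
GSM614354	GSE25009	30
GSM614355	GSE25009	60
GSM614356	GSE25009	60
GSM614357	GSE25009	60
GSM644354	GSE26246	0
GSM644355	GSE26246	0
GSM644356	GSE26246	0
GSM644357	GSE26246	2
GSM644358	GSE26246	2
GSM644359	GSE26246	2
GSM644360	GSE26246	14
GSM644361	GSE26246	14
GSM644362	GSE26246	14
GSM658027	GSE26726	10
GSM658028	GSE26726	10
GSM658029	GSE26726	10
GSM658036	GSE26726	10
GSM658037	GSE26726	10
GSM658038	GSE26726	10
GSM658060	GSE26726	10
GSM658061	GSE26726	10
GSM658062	GSE26726	10
GSM658042	GSE26726	40
GSM658043	GSE26726	40
GSM658044	GSE26726	40
GSM658051	GSE26726	40
GSM658052	GSE26726	40
GSM658053	GSE26726	40
GSM658066	GSE26726	40
GSM658067	GSE26726	40
GSM658068	GSE26726	40
GSM557543	GSE22440	10
GSM557544	GSE22440	10
GSM557545	GSE22440	10
GSM557546	GSE22440	40
GSM557547	GSE22440	40
GSM557548	GSE22440	40
GSM530094	GSE21182	1
GSM530096	GSE21182	40
GSM132562	GSE6314	15
GSM132563	GSE6314	15
GSM132564	GSE6314	20
GSM132565	GSE6314	20
GSM132566	GSE6314	30
GSM132567	GSE6314	30
GSM132568	GSE6314	45
GSM132569	GSE6314	45
GSM132570	GSE6314	60
GSM132571	GSE6314	60
GSM12770	GSE826	3
GSM12772	GSE826	47
GSM912518	GSE37148	5
GSM912519	GSE37148	5
GSM912520	GSE37148	5
GSM912521	GSE37148	45
GSM912522	GSE37148	45
GSM912523	GSE37148	45
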