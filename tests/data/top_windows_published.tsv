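obs	window	start_snp	end_snp	n_snp	pct_var	cum_var	chr_mb	top_snp	model_freq	t_like	stand_effect
1	1621	ARS-BFGL-BAC-27751	ARS-BFGL-NGS-115263	17	1.67	1.67	15_37	ARS-BFGL-NGS-5811	0.7574	1.393	1.4036
2	1319	ARS-BFGL-NGS-112243	ARS-BFGL-NGS-12954	17	1.19	2.86	11_101	ARS-BFGL-NGS-111179	0.6731	1.243	1.135
3	1164	ARS-BFGL-NGS-1854	ARS-BFGL-NGS-24556	27	1.13	3.99	10_51	Hapmap58695-rs29019899	0.5048	1.076	0.8828
4	1553	ARS-BFGL-NGS-115527	ARS-BFGL-NGS-1112	15	0.84	4.83	14_54	BTB-00915241	0.3045	0.982	0.4614
5	710	BTB-01688071	ARS-BFGL-NGS-58275	23	0.78	5.6	6_49	BTB-02002785	0.3176	0.986	0.4781
6	1283	ARS-BFGL-NGS-44192	Hapmap60779-rs29022104	14	0.74	6.35	11_65	Hapmap60779-rs29022104	0.3697	1.005	0.6143
7	531	Hapmap57291-ss46526771	Hapmap22875-BTA-155031	14	0.74	7.09	4_113	Hapmap22875-BTA-155031	0.4834	1.06	0.8291
8	553	Hapmap36482-SCAFFOLD163485_1458	BTA-87049-no-rs	12	0.68	7.77	5_14	Hapmap52967-rs29017027	0.4047	1.022	0.621
9	1974	ARS-BFGL-NGS-13160	BTB-00774670	20	0.64	8.4	20_17	Hapmap34041-BES1_Contig298_838	0.327	0.988	0.5321
10	1429	Hapmap48542-BTA-97857	ARS-BFGL-NGS-27497	11	0.54	8.95	13_14	Hapmap44228-BTA-34185	0.3342	0.99	0.496
11	1488	ARS-BFGL-NGS-107401	ARS-BFGL-NGS-4602	18	0.53	9.48	13_73	Hapmap40517-BTA-33731	0.3514	0.997	0.5201
12	1709	Hapmap54735-ss46526095	Hapmap56619-rs29009970	16	0.52	10	16_40	ARS-BFGL-NGS-40365	0.2408	0.956	0.3808
13	214	Hapmap25908-BTA-160304	Hapmap60963-rs29015781	26	0.47	10.47	2_55	ARS-BFGL-NGS-111213	0.1665	0.937	0.2428
14	1159	ARS-BFGL-NGS-113665	ARS-BFGL-NGS-10383	21	0.46	10.93	10_46	ARS-BFGL-NGS-60054	0.2224	0.953	0.3154
15	944	Hapmap41647-BTA-81135	ARS-BFGL-NGS-111988	20	0.46	11.39	8_50	BTB-01398754	0.0986	0.902	0.1449
16	1495	ARS-BFGL-NGS-83969	Hapmap41120-BTA-99310	20	0.46	11.85	13_80	Hapmap41120-BTA-99310	0.1838	0.942	0.2532
17	293	ARS-BFGL-NGS-22691	ARS-BFGL-NGS-17681	22	0.43	12.28	2_134	ARS-BFGL-NGS-113378	0.2608	0.956	0.4564
18	179	ARS-BFGL-NGS-39206	BTB-01168392	21	0.41	12.69	2_20	BTB-00082871	0.2273	0.953	0.3302
19	1001	Hapmap25843-BTA-146186	ARS-BFGL-NGS-20859	18	0.37	13.07	8_107	Hapmap40677-BTA-121871	0.1692	0.936	0.2455
20	2440	BTB-00980670	Hapmap34915-BES7_Contig278_1082	17	0.32	13.39	28_20	BTB-01129090	0.1208	0.923	0.153
21	2028	Hapmap44700-BTA-34998	ARS-BFGL-NGS-118166	15	0.32	13.71	20_71	ARS-BFGL-NGS-13702	0.2361	0.947	0.3888
22	163	Hapmap43083-BTA-86781	BTA-47785-no-rs	17	0.3	14.01	2_4	BTB-00077766	0.1948	0.944	0.2567
23	1132	ARS-BFGL-NGS-94247	ARS-BFGL-NGS-32828	24	0.28	14.29	10_18	ARS-BFGL-NGS-107048	0.2059	0.947	0.3001
24	147	Hapmap30204-BTA-124882	BTB-01761180	28	0.28	14.57	1_147	BTB-01301015	0.1687	0.934	0.2423
25	515	Hapmap25270-BTA-142450	ARS-BFGL-NGS-12738	11	0.28	14.85	4_97	Hapmap25270-BTA-142450	0.1796	0.931	0.296
26	1239	Hapmap43962-BTA-86597	Hapmap42711-BTA-87541	24	0.26	15.11	11_21	BTB-00464454	0.142	0.926	0.21
27	1238	ARS-BFGL-NGS-20053	BTB-00464777	19	0.26	15.37	11_20	BTA-104373-no-rs	0.1533	0.922	0.228
28	290	ARS-BFGL-NGS-54356	ARS-BFGL-NGS-77887	26	0.26	15.63	2_131	BTB-00117780	0.1469	0.931	0.1938
29	664	Hapmap30828-BTA-143720	Hapmap30881-BTA-159706	23	0.25	15.88	6_3	Hapmap30881-BTA-159706	0.171	0.937	0.2465
30	2515	Hapmap24672-BTA-140771	ARS-BFGL-NGS-29493	27	0.25	16.13	29_48	BTA-66199-no-rs	0.211	0.951	0.2818
31	329	ARS-BFGL-NGS-117560	Hapmap51025-BTA-67309	19	0.25	16.38	3_33	ARS-BFGL-NGS-119309	0.0962	0.91	0.1189
32	1758	ARS-BFGL-NGS-5880	BTA-122662-no-rs	23	0.25	16.63	17_7	ARS-BFGL-BAC-27352	0.1857	0.944	0.2496
33	2013	ARS-BFGL-NGS-55465	Hapmap51244-BTA-50863	19	0.24	16.87	20_56	Hapmap43377-BTA-85612	0.1385	0.927	0.1717
34	442	ARS-BFGL-NGS-113848	BTB-00169886	16	0.24	17.12	4_24	Hapmap45129-BTA-72713	0.1427	0.925	0.2042
35	1485	ARS-BFGL-NGS-118627	ARS-BFGL-BAC-15769	17	0.24	17.35	13_70	Hapmap57013-rs29019369	0.1502	0.934	0.1073
36	1656	ARS-BFGL-BAC-18252	Hapmap45825-BTA-25376	16	0.23	17.58	15_72	Hapmap45825-BTA-25376	0.1828	0.943	0.2411
37	261	Hapmap48190-BTA-114376	BTA-48503-no-rs	11	0.23	17.81	2_102	Hapmap36094-SCAFFOLD96944_22403	0.1323	0.928	0.1683
38	1190	ARS-BFGL-NGS-38839	Hapmap50492-BTA-86239	16	0.23	18.04	10_77	ARS-BFGL-NGS-111871	0.1883	0.945	0.2477
39	2294	ARS-BFGL-NGS-26313	ARS-BFGL-NGS-34801	17	0.23	18.26	25_15	ARS-BFGL-NGS-84660	0.1403	0.933	0.1543
40	2309	ARS-BFGL-BAC-3777	ARS-BFGL-BAC-47171	21	0.23	18.49	25_30	ARS-BFGL-BAC-37178	0.1584	0.911	0.3051
41	665	ARS-BFGL-NGS-56212	BTB-01468045	20	0.22	18.71	6_4	BTB-01280976	0.0959	0.922	0.1089
42	794	ARS-BFGL-NGS-93802	Hapmap57279-ss46526160	19	0.22	18.93	7_13	ARS-BFGL-NGS-111257	0.0898	0.91	0.1073
43	484	ARS-BFGL-NGS-26541	ARS-BFGL-NGS-44674	20	0.21	19.14	4_66	ARS-BFGL-NGS-36591	0.1501	0.932	0.2019
44	1976	BTB-00775794	Hapmap49633-BTA-50009	16	0.21	19.35	20_19	Hapmap28040-BTA-134983	0.1529	0.935	0.21
45	1743	BTB-00661933	ARS-BFGL-NGS-99802	17	0.2	19.56	16_74	Hapmap48746-BTA-40116	0.1664	0.938	0.2172
46	282	ARS-BFGL-NGS-102874	ARS-BFGL-NGS-15468	22	0.2	19.76	2_123	ARS-BFGL-NGS-102874	0.1163	0.915	0.1622
47	2146	ARS-BFGL-NGS-118471	Hapmap38075-BTA-54630	18	0.2	19.96	22_45	BTB-00849206	0.1658	0.922	0.2876
48	364	BTA-68264-no-rs	Hapmap44273-BTA-68311	24	0.2	20.15	3_68	ARS-BFGL-NGS-33433	0.1601	0.912	0.2923
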