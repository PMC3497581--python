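n	u_0.01	u_0.05	u_0.1	u_0.5	u_0.9	u_0.95	u_0.99
4	221.437	186.480	167.832	111.658	61.513	48.992	28.720
5	211.991	183.591	168.715	116.223	69.942	58.781	39.669
6	206.806	180.607	166.277	118.898	76.616	65.763	47.430
7	202.664	177.752	165.109	121.146	81.206	71.005	53.636
8	198.556	175.665	163.613	122.690	85.221	75.617	58.473
9	195.052	173.431	162.271	123.838	88.426	79.138	62.797
10	192.604	172.049	161.297	124.718	91.044	82.073	66.810
11	189.812	170.350	160.155	125.349	93.271	84.754	69.277
12	187.684	169.182	159.485	126.047	95.148	86.846	72.006
13	185.431	167.652	158.314	126.424	96.644	88.607	74.483
14	183.837	166.737	157.663	127.115	98.339	90.643	76.796
15	182.089	165.804	157.076	127.134	99.473	91.964	78.378
16	180.995	164.796	156.366	127.576	100.718	93.540	80.656
17	179.670	164.065	155.796	127.913	101.704	94.518	81.788
18	178.180	163.238	155.344	128.145	102.718	95.882	83.551
19	177.095	162.465	154.680	128.390	103.648	96.844	84.811
20	175.792	161.921	154.355	128.658	104.327	97.766	86.059
21	174.836	161.141	153.835	128.803	105.084	98.574	86.891
22	174.288	160.583	153.586	129.009	105.793	99.493	88.060
23	173.226	160.008	153.138	129.135	106.380	100.243	89.005
24	172.349	159.377	152.610	129.283	107.090	101.052	90.055
25	171.433	158.864	152.295	129.425	107.608	101.663	90.829
26	170.897	158.507	151.996	129.532	108.190	102.377	91.685
27	170.745	158.236	151.786	129.688	108.699	102.989	92.436
28	169.526	157.634	151.386	129.771	109.180	103.462	93.277
29	169.116	157.310	151.100	129.803	109.546	103.957	93.826
30	168.108	156.783	150.764	129.820	109.955	104.567	94.568
31	167.640	156.477	150.468	130.009	110.426	104.946	95.114
32	167.265	156.032	150.244	130.023	110.651	105.323	95.713
33	167.076	155.863	150.068	130.220	111.149	105.933	96.218
34	166.212	155.500	149.877	130.252	111.423	106.325	96.827
35	165.902	155.183	149.537	130.340	111.822	106.744	97.533
36	165.204	154.957	149.424	130.328	112.014	107.007	97.715
37	164.964	154.547	149.107	130.372	112.360	107.378	98.364
38	164.592	154.484	149.044	130.446	112.662	107.751	98.919
39	163.992	154.134	148.834	130.485	112.974	108.081	99.130
40	163.912	153.804	148.549	130.470	113.188	108.490	99.614
41	163.306	153.525	148.375	130.564	113.420	108.768	100.282
42	162.808	153.360	148.244	130.614	113.742	109.127	100.542
43	162.579	153.157	148.031	130.660	114.002	109.341	100.897
44	162.299	152.866	147.888	130.703	114.116	109.583	101.395
45	161.859	152.637	147.776	130.740	114.407	109.885	101.653
46	161.667	152.510	147.600	130.784	114.633	110.148	101.898
47	161.327	152.232	147.423	130.827	114.719	110.362	102.180
48	161.250	152.114	147.346	130.902	115.003	110.557	102.413
49	160.714	151.950	147.220	130.865	115.182	110.870	102.888
50	160.394	151.591	146.956	130.923	115.445	111.119	103.176
51	160.319	151.537	146.955	130.956	115.595	111.291	103.560
52	159.791	151.309	146.779	131.006	115.833	111.583	103.847
53	159.761	151.222	146.716	131.047	115.885	111.680	103.807
54	159.496	150.970	146.519	131.010	116.090	111.867	104.105
55	159.530	150.865	146.383	131.101	116.209	112.011	104.464
56	158.942	150.597	146.174	131.039	116.396	112.358	104.693
57	158.876	150.592	146.211	131.123	116.527	112.493	105.026
58	158.663	150.491	146.080	131.171	116.685	112.733	105.298
59	158.435	150.238	145.988	131.181	116.725	112.778	105.382
60	158.021	150.140	145.872	131.189	116.992	113.056	105.679
61	157.949	149.983	145.795	131.244	117.146	113.204	105.977
62	157.761	149.862	145.669	131.229	117.235	113.368	106.250
63	157.584	149.687	145.539	131.240	117.405	113.515	106.368
64	157.168	149.503	145.454	131.271	117.509	113.663	106.631
65	157.243	149.487	145.449	131.251	117.603	113.842	106.859
66	156.855	149.302	145.295	131.273	117.652	113.901	106.892
67	156.885	149.335	145.265	131.324	117.878	114.142	107.143
68	156.571	149.093	145.071	131.303	117.840	114.143	107.348
69	156.573	149.001	145.104	131.384	118.039	114.364	107.571
70	156.146	148.785	144.993	131.399	118.129	114.449	107.910
71	155.971	148.803	144.956	131.414	118.234	114.603	107.870
72	155.974	148.708	144.790	131.401	118.410	114.767	108.162
73	155.891	148.490	144.650	131.418	118.459	114.934	108.338
74	155.713	148.397	144.604	131.429	118.583	115.041	108.541
75	155.355	148.361	144.581	131.456	118.698	115.173	108.715
76	155.302	148.106	144.424	131.496	118.840	115.324	108.802
77	155.140	148.068	144.331	131.430	118.867	115.356	108.904
78	155.046	148.061	144.312	131.439	118.930	115.409	109.116
79	154.988	147.839	144.192	131.440	118.977	115.552	109.036
80	154.702	147.821	144.178	131.507	119.193	115.717	109.382
81	154.679	147.758	144.089	131.470	119.163	115.767	109.667
82	154.570	147.727	144.092	131.547	119.280	115.961	109.722
83	154.397	147.584	144.017	131.487	119.390	116.011	109.722
84	154.309	147.512	143.928	131.582	119.492	116.150	110.019
85	154.092	147.398	143.852	131.553	119.512	116.177	109.970
86	153.956	147.325	143.817	131.528	119.620	116.311	110.202
87	153.756	147.215	143.751	131.575	119.734	116.432	110.355
88	153.712	147.139	143.685	131.609	119.802	116.532	110.424
89	153.694	147.113	143.617	131.574	119.866	116.618	110.659
90	153.520	147.031	143.553	131.621	119.979	116.701	110.664
91	153.398	146.863	143.445	131.621	119.999	116.763	110.817
92	153.208	146.875	143.492	131.605	120.075	116.858	110.900
93	153.306	146.850	143.403	131.627	120.148	117.008	111.109
94	153.180	146.741	143.387	131.661	120.226	117.080	111.110
95	152.932	146.564	143.225	131.625	120.285	117.104	111.140
96	152.937	146.566	143.205	131.626	120.396	117.251	111.456
97	152.754	146.530	143.171	131.670	120.455	117.316	111.492
98	152.624	146.435	143.116	131.672	120.465	117.330	111.659
99	152.500	146.269	143.025	131.669	120.555	117.471	111.691
100	152.412	146.265	143.016	131.671	120.646	117.555	111.948
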