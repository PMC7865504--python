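network	group	nodes	edges	mean_connectivity	mean_degree	mean_closeness	mean_betweenness	diameter	mean_minimal_distance	mean_page_rank	hub_nodes	centralization	transitivity
Ca Renal (U)	cancer	203	1939	0.407	0.095	0.348	0.009	6	2.886	0.005	95	0.163	0.191
Co Renal (U)	control	203	1889	0.435	0.092	0.344	0.010	5	2.920	0.005	100	0.225	0.195
Ca Liver (S)	cancer	62	229	0.547	0.121	0.205	0.067	11	5.003	0.016	43	0.207	0.036
Co Liver (S)	control	62	191	0.428	0.101	0.051	0.036	11	4.489	0.016	40	0.129	0.025
Ca Liver (U)	cancer	77	357	0.373	0.122	0.081	0.028	9	3.588	0.013	46	0.220	0.247
Co Liver (U)	control	77	289	0.355	0.099	0.076	0.036	10	4.394	0.013	40	0.164	0.149
Ca Lung (T) B20	cancer	91	632	0.272	0.154	0.152	0.026	8	3.484	0.011	14	0.223	0.457
Co Lung (T) B20	control	91	612	0.263	0.149	0.135	0.023	8	3.239	0.011	15	0.295	0.372
Ca Prostate (T)	cancer	72	294	0.168	0.115	0.052	0.045	16	5.513	0.014	9	0.167	0.447
Co Prostate (T)	control	72	276	0.148	0.108	0.065	0.049	12	5.493	0.014	21	0.117	0.482
Ca Gastric (P)	cancer	103	10204	2.072	1.943	0.243	0.000	1	1.000	0.010	0	2.018	1.000
Co Gastric (P)	control	103	10004	2.225	1.904	0.193	0.000	1	1.000	0.010	0	2.017	1.000
Ca Breast (P) B16	cancer	68	585	1.094	0.257	0.436	0.020	4	2.307	0.015	39	0.131	0.157
Co Breast (P) B16	control	68	637	1.078	0.280	0.449	0.019	4	2.238	0.015	28	0.168	0.185
Ca Breast (T)	cancer	65	499	0.566	0.240	0.370	0.028	5	2.750	0.015	8	0.229	0.334
Co Breast (T)	control	65	293	0.409	0.141	0.106	0.042	10	4.130	0.015	23	0.234	0.397
Ca MM (T)	cancer	191	3171	0.233	0.175	0.334	0.011	6	3.073	0.005	13	0.404	0.613
Co MM (T)	control	191	2807	0.217	0.155	0.328	0.011	6	3.065	0.005	1	0.151	0.506
Ca Colorectal (S)	cancer	113	813	0.650	0.128	0.347	0.017	6	2.911	0.009	59	0.122	0.169
Co Colorectal (S)	control	113	713	0.710	0.113	0.327	0.019	7	3.100	0.009	69	0.084	0.141
Ca Breast (P) B15	cancer	221	2863	0.941	0.118	0.389	0.007	4	2.585	0.005	78	0.146	0.215
Co Breast (P) B15	control	221	2857	0.853	0.118	0.389	0.007	5	2.581	0.005	78	0.110	0.224
Ca Breast (S)	cancer	260	3778	0.667	0.112	0.390	0.006	5	2.581	0.004	89	0.228	0.215
Co Breast (S)	control	260	3500	0.463	0.104	0.377	0.006	6	2.675	0.004	69	0.143	0.233
Ca Lung (T) ST390	cancer	182	1614	0.732	0.098	0.261	0.010	5	2.831	0.005	123	0.101	0.153
Co Lung (T) ST390	control	182	2116	0.274	0.128	0.258	0.010	6	2.885	0.005	19	0.225	0.398
Ca Lung (P)	cancer	126	878	0.460	0.111	0.247	0.016	7	3.055	0.008	62	0.113	0.189
Co Lung (P)	control	126	914	0.833	0.116	0.169	0.014	5	2.844	0.008	98	0.140	0.110
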