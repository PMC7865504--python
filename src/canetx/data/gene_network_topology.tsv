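network	group	nodes	edges	mean_connectivity	mean_degree	mean_closeness	mean_betweenness	diameter	mean_minimal_distance	mean_page_rank	hub_nodes	centralization	transitivity
Ca Renal	cancer	2570	148296	0.811	0.045	0.433	0.001	3	2.311	0.000	2347	0.040	0.082
Co Renal	control	2570	164272	0.576	0.050	0.440	0.000	3	2.277	0.000	2055	0.086	0.121
Ca Gastric	cancer	2570	111026	1.273	0.034	0.398	0.001	4	2.513	0.000	2349	0.040	0.063
Co Gastric	control	2570	163932	0.366	0.050	0.425	0.001	4	2.357	0.000	1508	0.087	0.209
Ca Prostate	cancer	2570	160446	0.627	0.049	0.442	0.000	3	2.267	0.000	2251	0.061	0.091
Co Prostate	control	2570	166152	0.629	0.050	0.443	0.000	3	2.262	0.000	2149	0.078	0.107
Ca Liver	cancer	2570	156934	0.922	0.048	0.441	0.000	3	2.270	0.000	2358	0.047	0.081
Co Liver	control	2570	151116	0.620	0.046	0.433	0.001	3	2.314	0.000	2228	0.061	0.090
Ca Colorectal	cancer	2570	108138	1.687	0.033	0.398	0.001	4	2.518	0.000	2484	0.033	0.041
Co Colorectal	control	2570	179636	0.666	0.054	0.449	0.000	3	2.232	0.000	1904	0.074	0.139
Ca Lung	cancer	2570	80344	1.440	0.024	0.371	0.001	4	2.695	0.000	2483	0.030	0.038
Co Lung	control	2570	168414	0.713	0.051	0.443	0.000	3	2.264	0.000	2063	0.073	0.117
Ca Breast	cancer	2570	50256	1.164	0.015	0.334	0.001	5	3.000	0.000	2512	0.018	0.034
Co Breast	control	2570	155668	0.812	0.047	0.438	0.001	3	2.286	0.000	2283	0.050	0.082
Ca MM	cancer	2570	145712	0.325	0.044	0.418	0.001	3	2.395	0.000	2067	0.087	0.158
Co MM	control	2570	356528	0.152	0.108	0.292	0.001	6	3.423	0.000	0	0.080	0.602
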