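id	species	subpop	lat	lon	coverage
OB-A_000	wild	OB-A	12.9757	-5.7556	16.39
OB-A_001	wild	OB-A	14.216	-4.8856	15.52
OB-A_002	wild	OB-A	12.2926	-4.4621	10.65
OB-A_003	wild	OB-A	12.5651	-5.3669	34.07
OB-A_004	wild	OB-A	11.0047	-4.9054	11.21
OB-A_005	wild	OB-A	13.2883	-4.9947	7.81
OB-A_006	wild	OB-A	12.3746	-4.6592	22.26
OB-A_007	wild	OB-A	12.1252	-5.2134	25.08
OB-A_008	wild	OB-A	12.7426	-5.6629	11.26
OB-A_009	wild	OB-A	13.1273	-5.6628	31.29
OB-B_010	wild	OB-B	10.2413	-2.6086	6.38
OB-B_011	wild	OB-B	11.6275	-1.5428	13.82
OB-B_012	wild	OB-B	11.0233	-2.0018	14.28
OB-B_013	wild	OB-B	11.937	-2.1532	20.66
OB-B_014	wild	OB-B	11.3277	-1.172	7.58
OB-B_015	wild	OB-B	10.0838	-1.9922	16.87
OB-B_016	wild	OB-B	10.7611	-3.2783	22.84
OB-B_017	wild	OB-B	11.4771	-2.2182	11.64
OB-B_018	wild	OB-B	10.4794	-2.2068	21.73
OB-B_019	wild	OB-B	11.4618	-2.8098	12.95
OB-C_020	wild	OB-C	13.2822	0.7564	25.12
OB-C_021	wild	OB-C	13.0934	0.9834	8.44
OB-C_022	wild	OB-C	13.5094	2.0693	15.29
OB-C_023	wild	OB-C	12.2569	1.2125	3.34
OB-C_024	wild	OB-C	12.7053	0.6219	12.07
OB-C_025	wild	OB-C	13.0647	0.1985	11.83
OB-C_026	wild	OB-C	12.4151	2.0336	20.03
OB-C_027	wild	OB-C	12.7653	1.0379	5.8
OB-C_028	wild	OB-C	12.8033	1.2883	14.4
OB-C_029	wild	OB-C	12.9996	0.2864	16.47
OB-D_030	wild	OB-D	11.716	4.8122	32.48
OB-D_031	wild	OB-D	12.8976	4.6746	11.99
OB-D_032	wild	OB-D	11.0264	4.7586	11.02
OB-D_033	wild	OB-D	11.9966	3.8573	18.3
OB-D_034	wild	OB-D	11.6807	4.6277	18.31
OB-D_035	wild	OB-D	12.6014	3.7536	28.99
OB-D_036	wild	OB-D	11.8011	4.0268	9.16
OB-D_037	wild	OB-D	12.8561	3.2188	29.83
OB-D_038	wild	OB-D	12.442	4.7163	7.37
OB-D_039	wild	OB-D	12.8816	2.5775	15.05
OG-1_040	dom	OG-1	15.1849	-16.735	7.03
OG-1_041	dom	OG-1	14.5374	-16.9335	16.39
OG-1_042	dom	OG-1	15.1725	-15.2348	17.68
OG-1_043	dom	OG-1	14.7559	-15.6967	12.97
OG-1_044	dom	OG-1	14.7418	-16.5964	10.2
OG-1_045	dom	OG-1	15.7498	-17.3537	10.46
OG-1_046	dom	OG-1	14.1197	-16.1779	18.49
OG-1_047	dom	OG-1	14.9905	-16.9201	11.53
OG-1_048	dom	OG-1	14.183	-16.7864	13.05
OG-2_049	dom	OG-2	10.7158	-15.2859	13.14
OG-2_050	dom	OG-2	11.8999	-14.0694	22.15
OG-2_051	dom	OG-2	11.6403	-14.9678	11.15
OG-2_052	dom	OG-2	11.873	-15.4072	12.35
OG-2_053	dom	OG-2	11.5616	-14.3957	18.44
OG-2_054	dom	OG-2	11.3594	-14.4091	16.87
OG-2_055	dom	OG-2	11.6352	-14.2501	24.23
OG-2_056	dom	OG-2	11.0624	-14.4171	25.73
OG-2_057	dom	OG-2	12.0558	-13.7635	16.22
OG-3_058	dom	OG-3	8.4399	-12.4951	19.84
OG-3_059	dom	OG-3	9.3092	-12.1688	17.83
OG-3_060	dom	OG-3	9.1379	-11.2544	10.37
OG-3_061	dom	OG-3	8.3479	-11.4916	19.31
OG-3_062	dom	OG-3	7.6573	-11.8973	20.78
OG-3_063	dom	OG-3	9.8473	-11.5918	12.99
OG-3_064	dom	OG-3	8.7711	-11.5775	31.73
OG-3_065	dom	OG-3	9.2987	-12.8079	2.85
OG-3_066	dom	OG-3	7.5485	-11.8041	11.86
OG-4_067	dom	OG-4	9.9693	-7.754	10.74
OG-4_068	dom	OG-4	11.8789	-7.6154	8.64
OG-4_069	dom	OG-4	11.3304	-6.5775	10.45
OG-4_070	dom	OG-4	10.9047	-7.6782	15.51
OG-4_071	dom	OG-4	10.9627	-7.0722	20.86
OG-4_072	dom	OG-4	11.6912	-7.5202	18.86
OG-4_073	dom	OG-4	10.6074	-7.7402	9.53
OG-4_074	dom	OG-4	11.6964	-7.884	12.61
OG-4_075	dom	OG-4	10.0047	-8.4373	15.35
OG-5_076	dom	OG-5	13.2584	-4.1253	25.43
OG-5_077	dom	OG-5	13.063	-4.1958	10.3
OG-5_078	dom	OG-5	12.7549	-4.0323	21.22
OG-5_079	dom	OG-5	13.1838	-4.6254	6.54
OG-5_080	dom	OG-5	12.9682	-4.24	12.02
OG-5_081	dom	OG-5	13.7316	-4.6393	4.49
OG-5_082	dom	OG-5	13.7653	-4.0166	10.41
OG-5_083	dom	OG-5	13.7436	-3.9141	31.16
OG-5_084	dom	OG-5	13.913	-3.1315	10.16
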