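gene	transcript	seq_length_bp	orf_length_aa	mw_kda	pi
PgSPL01	PgSPL01	231	65	7.22	8.79
PgSPL02	PgSPL02	529	88	10.08	4.81
PgSPL03	PgSPL03	988	182	20.32	8.74
PgSPL04	PgSPL04	2342	692	77.39	6.76
PgSPL05	PgSPL05	280	76	9.28	10.73
PgSPL06	PgSPL06	254	76	8.83	9.84
PgSPL07	PgSPL07	216	58	6.53	8.88
PgSPL08	PgSPL08	3216	961	105.47	5.67
PgSPL09	PgSPL09	264	81	8.81	9.64
PgSPL10	PgSPL10	1037	199	21.92	8.83
PgSPL11	PgSPL11	3582	966	106.26	6.82
PgSPL12	PgSPL12-01	511	63	6.56	4.58
PgSPL12	PgSPL12-02	523	66	6.80	4.58
PgSPL13	PgSPL13	832	74	8.56	11.40
PgSPL14	PgSPL14	1097	210	22.96	9.03
PgSPL15	PgSPL15	439	67	7.28	4.33
PgSPL16	PgSPL16	930	198	22.16	8.91
PgSPL17	PgSPL17-01	4180	264	29.47	6.25
PgSPL17	PgSPL17-04	4149	307	35.33	6.19
PgSPL17	PgSPL17-05	3882	264	29.47	6.25
PgSPL18	PgSPL18	1146	378	41.28	9.52
PgSPL19	PgSPL19	684	182	20.82	9.77
PgSPL20	PgSPL20-01	982	65	7.47	5.68
PgSPL20	PgSPL20-10	994	307	34.87	8.66
PgSPL20	PgSPL20-03	1779	65	7.47	5.68
PgSPL20	PgSPL20-04	1697	307	34.33	8.72
PgSPL20	PgSPL20-05	1685	307	34.87	8.66
PgSPL20	PgSPL20-06	1786	307	34.87	8.66
PgSPL20	PgSPL20-08	1791	307	34.87	8.66
PgSPL20	PgSPL20-09	1798	307	34.33	8.72
PgSPL21	PgSPL21-11	2176	213	22.94	9.78
PgSPL21	PgSPL21-13	2164	213	22.94	9.78
PgSPL21	PgSPL21-16	2206	213	22.94	9.78
PgSPL21	PgSPL21-18	2218	213	22.94	9.78
PgSPL22	PgSPL22-01	1827	384	42.24	8.26
PgSPL22	PgSPL22-02	1751	384	42.25	8.01
PgSPL22	PgSPL22-03	1691	380	41.86	7.61
PgSPL22	PgSPL22-04	1827	384	42.24	8.26
PgSPL22	PgSPL22-05	1735	384	42.26	8.26
PgSPL23	PgSPL23-01	1046	247	27.33	7.64
PgSPL23	PgSPL23-35	454	70	7.95	9.50
PgSPL24	PgSPL24-01	531	68	7.79	6.79
PgSPL24	PgSPL24-10	1312	186	21.35	8.77
PgSPL24	PgSPL24-11	1968	126	14.21	6.95
PgSPL24	PgSPL24-13	1211	186	21.35	8.77
PgSPL24	PgSPL24-14	776	177	20.27	8.76
PgSPL24	PgSPL24-15	1783	177	20.25	8.77
PgSPL24	PgSPL24-16	680	95	11.58	9.35
PgSPL24	PgSPL24-19	1026	68	7.79	6.79
PgSPL24	PgSPL24-03	1155	61	6.87	9.94
PgSPL24	PgSPL24-05	1127	95	11.58	9.35
PgSPL24	PgSPL24-07	1187	58	6.68	10.23
PgSPL24	PgSPL24-09	430	136	15.59	8.68
PgSPL25	PgSPL25-01	2764	533	58.86	8.29
PgSPL25	PgSPL25-10	2408	533	58.86	8.29
PgSPL25	PgSPL25-08	2606	537	59.32	8.10
PgSPL26	PgSPL26-01	2025	469	50.92	8.14
PgSPL26	PgSPL26-10	2377	469	50.90	8.14
PgSPL26	PgSPL26-11	1844	469	50.90	8.14
PgSPL26	PgSPL26-12	1932	469	50.90	8.14
PgSPL26	PgSPL26-13	2484	469	50.90	8.14
PgSPL26	PgSPL26-16	2044	469	50.90	8.14
PgSPL26	PgSPL26-17	2391	469	50.90	8.14
PgSPL26	PgSPL26-18	2591	469	50.92	8.14
PgSPL26	PgSPL26-19	1860	469	50.90	8.14
PgSPL26	PgSPL26-02	2288	469	50.92	8.14
PgSPL26	PgSPL26-20	2407	469	50.90	8.14
PgSPL26	PgSPL26-21	1948	469	50.92	8.14
PgSPL26	PgSPL26-22	2177	469	50.92	8.14
PgSPL26	PgSPL26-03	1955	469	50.90	8.14
PgSPL26	PgSPL26-04	2193	469	50.90	8.14
PgSPL26	PgSPL26-05	2270	469	50.92	8.14
PgSPL26	PgSPL26-06	2043	469	50.92	8.14
PgSPL26	PgSPL26-07	2502	469	50.90	8.14
PgSPL26	PgSPL26-08	1937	469	50.92	8.14
PgSPL26	PgSPL26-09	2132	469	50.90	8.14
PgSPL27	PgSPL27-01	3029	795	88.78	6.53
PgSPL27	PgSPL27-11	2821	446	50.05	7.56
PgSPL27	PgSPL27-03	2879	447	50.07	7.57
PgSPL27	PgSPL27-04	2886	791	88.44	6.61
PgSPL27	PgSPL27-06	2864	446	50.05	7.56
PgSPL27	PgSPL27-07	2828	786	87.97	6.32
PgSPL27	PgSPL27-08	2806	446	50.05	7.56
PgSPL27	PgSPL27-09	3051	446	50.05	7.56
PgSPL28	PgSPL28-11	467	110	12.45	8.97
PgSPL28	PgSPL28-13	614	83	9.54	10.51
PgSPL28	PgSPL28-18	509	247	27.25	5.74
PgSPL28	PgSPL28-19	480	120	13.28	8.97
PgSPL28	PgSPL28-20	1085	249	27.64	6.32
PgSPL28	PgSPL28-27	680	120	13.28	8.97
PgSPL28	PgSPL28-28	1092	50	5.90	9.40
PgSPL28	PgSPL28-03	693	72	8.27	5.25
PgSPL28	PgSPL28-30	509	111	12.48	8.97
PgSPL28	PgSPL28-35	575	65	7.84	9.42
PgSPL28	PgSPL28-38	538	111	12.48	8.97
PgSPL28	PgSPL28-06	588	119	13.25	8.97
PgSPL29	PgSPL29	3288	828	91.11	6.17
PgSPL30	PgSPL30-01	1106	157	17.03	5.68
PgSPL30	PgSPL30-10	878	113	12.89	8.47
PgSPL30	PgSPL30-12	695	104	11.25	5.40
PgSPL30	PgSPL30-02	1631	113	12.89	8.47
PgSPL30	PgSPL30-03	1414	90	10.33	9.10
PgSPL30	PgSPL30-05	1328	210	22.32	5.79
PgSPL30	PgSPL30-07	1162	210	22.32	5.79
PgSPL30	PgSPL30-08	998	157	17.03	5.68
PgSPL30	PgSPL30-09	859	157	16.54	5.51
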