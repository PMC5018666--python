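gene	sequence_id	chromosome	group	at_orthologs	pt_orthologs	length_aa	pi	mw_kda	introns
SsWRKY1	willow_GLEAN_10011238	1	I	33	17	583	7.14	64.7	4
SsWRKY2	willow_GLEAN_10019192	1	IIc	45	43	162	9.47	18.6	1
SsWRKY3	willow_GLEAN_10017208	1	IIc	28,71	29	584	9.42	65.6	4
SsWRKY4	willow_GLEAN_10017139	1	I	20	44	560	6.99	60.9	5
SsWRKY5	willow_GLEAN_10007860	1	IIe	35	45	445	5.92	48.4	2
SsWRKY6	willow_GLEAN_10003806	1	I	2	37,101,102	733	5.69	78.8	4
SsWRKY7	willow_GLEAN_10022392	2	IId	21	46,63	453	9.53	49.9	4
SsWRKY8	willow_GLEAN_10022273	2	IIc	71	47	328	6.89	37.0	2
SsWRKY9	willow_GLEAN_10009329	2	IId	15	14,94	339	9.77	37.5	2
SsWRKY10	willow_GLEAN_10009231	2	IIc	12	48	204	7.64	23.6	3
SsWRKY11	willow_GLEAN_10016913	2	III	30	6,51	351	6.27	39.2	2
SsWRKY12	willow_GLEAN_10016886	2	IIc	–	19,50	129	6.75	14.6	0
SsWRKY13	willow_GLEAN_10016883	2	IIe	22	23,49,78	352	5.81	38.3	2
SsWRKY14	willow_GLEAN_10019911	2	IIe	–	3	247	5.58	28.1	2
SsWRKY15	willow_GLEAN_10019925	2	IIc	23	13,33	319	6.46	35.6	2
SsWRKY16	willow_GLEAN_10019982	2	I	1	54	472	6.88	52.2	3
SsWRKY17	willow_GLEAN_10020022	2	IIb	47	53	1081	5.25	116.8	17
SsWRKY18	willow_GLEAN_10025583	3	IId	–	55	142	9.60	16.5	2
SsWRKY19	willow_GLEAN_10025423	3	IIe	29	41	335	5.54	37.9	2
SsWRKY20	willow_GLEAN_10025378	3	III	41/53	21	342	5.25	38.4	2
SsWRKY21	willow_GLEAN_10008020	3	IIc	45	18	157	9.41	17.8	1
SsWRKY22	willow_GLEAN_10006448	3	IIa	40	88	320	8.38	35.4	3
SsWRKY23	willow_GLEAN_10013342	3	IIc	–	39	109	8.03	12.9	1
SsWRKY24	willow_GLEAN_10009960	4	IIb	42	28,79	604	6.93	65.3	5
SsWRKY25	willow_GLEAN_10017267	4	IIe	65	8,58	267	5.43	29.7	2
SsWRKY26	willow_GLEAN_10018559	4	I	58	60	537	8.72	58.9	3
SsWRKY27	willow_GLEAN_10004854	4	III	54	85	323	5.70	36.3	2
SsWRKY28	willow_GLEAN_10008312	5	IId	–	–	490	10.27	54.0	2
SsWRKY29	willow_GLEAN_10009112	5	IIc	13	68	235	8.70	26.7	2
SsWRKY30	willow_GLEAN_10003565	5	IId	15	20	310	9.48	34.3	2
SsWRKY31	willow_GLEAN_10016009	5	IIc	28,71	62	322	6.67	36.2	2
SsWRKY32	willow_GLEAN_10018195	5	IId	21	46,63	349	9.69	38.8	2
SsWRKY33	willow_GLEAN_10026833	6	IId	7	91	339	9.89	36.8	3
SsWRKY34	willow_GLEAN_10026721	6	IIc	49	34	287	5.25	32.1	2
SsWRKY35	willow_GLEAN_10026591	6	I	33	64	572	6.41	62.7	4
SsWRKY36	willow_GLEAN_10026566	6	III	54	85	329	6.13	36.7	2
SsWRKY37	willow_GLEAN_10020588	6	I	44	93	478	9.25	52.5	4
SsWRKY38	willow_GLEAN_10026166	6	IIc	51	67	233	5.03	26.1	2
SsWRKY39	willow_GLEAN_10026455	6	IIa	18/60	9	327	9.02	36.2	4
SsWRKY40	willow_GLEAN_10026458	6	I	32	15	413	8.26	44.9	3
SsWRKY41	willow_GLEAN_10008192	7	IIc	13	68	236	9.21	26.6	2
SsWRKY42	willow_GLEAN_10025108	8	I	3/4	69	460	8.80	50.6	3
SsWRKY43	willow_GLEAN_10025123	8	IIc	57	71	295	6.32	32.3	2
SsWRKY44	willow_GLEAN_10015641	8	IIc	48	70	357	6.11	39.9	2
SsWRKY45	willow_GLEAN_10008155	9	IId	15	20,26	331	9.57	36.4	2
SsWRKY46	willow_GLEAN_10013562	10	IIc	57	71	289	6.26	31.9	2
SsWRKY47	willow_GLEAN_10013586	10	I	3/4	72	490	8.60	53.7	3
SsWRKY48	willow_GLEAN_10004012	11	IIb	42	100	585	6.48	63.3	5
SsWRKY49	willow_GLEAN_10006060	11	I	20	44	607	7.09	6.6	6
SsWRKY50	willow_GLEAN_10007614	11	IIe	35	74	481	5.39	51.6	3
SsWRKY51	willow_GLEAN_10007542	11	I	2	37	734	6.10	79.7	4
SsWRKY52	willow_GLEAN_10013801	12	IIc	–	75	178	9.08	20.5	1
SsWRKY53	willow_GLEAN_10012158	13	IId	74	25	356	9.66	40.0	2
SsWRKY54	willow_GLEAN_10004417	13	I	2	35	697	6.52	76.1	4
SsWRKY55	willow_GLEAN_10007732	13	I	33	1	602	7.65	66.0	4
SsWRKY56	willow_GLEAN_10009039	14	IId	15	14,94	362	9.39	40.0	2
SsWRKY57	willow_GLEAN_10016668	14	IIc	12	48	180	8.47	20.7	3
SsWRKY58	willow_GLEAN_10016177	14	IIe	22	23,49,78	354	6.35	38.8	2
SsWRKY59	willow_GLEAN_10016180	14	IIc	43	19,50	193	9.47	21.7	1
SsWRKY60	willow_GLEAN_10016220	14	III	30	6	368	5.03	41.3	2
SsWRKY61	willow_GLEAN_10018940	14	IIb	42	28,79	467	8.78	50.0	5
SsWRKY62	willow_GLEAN_10018891	14	IIc	23	13,33	318	5.71	35.6	2
SsWRKY63	willow_GLEAN_10018881	14	IIe	–	80	263	5.05	29.7	2
SsWRKY64	willow_GLEAN_10020302	14	IIb	36	–	460	6.28	50.0	4
SsWRKY65	willow_GLEAN_10020380	14	I	1	2	481	5.98	52.8	3
SsWRKY66	willow_GLEAN_10011119	15	IIb	9	99	618	6.55	66.2	5
SsWRKY67	willow_GLEAN_10016438	15	IIc	–	82	178	9.35	20.5	1
SsWRKY68	willow_GLEAN_10023347	16	IIa	40	88	320	8.82	35.3	3
SsWRKY69	willow_GLEAN_10023447	16	IIc	45	18	178	9.17	20.1	1
SsWRKY70	willow_GLEAN_10023687	16	III	41/53	21	336	5.17	37.2	2
SsWRKY71	willow_GLEAN_10023735	16	IIe	29	41	325	5.54	36.6	2
SsWRKY72	willow_GLEAN_10014752	16	IId	–	55	338	9.24	37.9	2
SsWRKY73	willow_GLEAN_10009602	16	IIb	9	42	509	5.51	55.3	4
SsWRKY74	willow_GLEAN_10010473	17	IIc	45	43	182	9.92	20.9	1
SsWRKY75	willow_GLEAN_10015128	17	IIb	9	86	544	6.01	59.0	3
SsWRKY76	willow_GLEAN_10015184	17	I	58	87	1044	8.94	116.1	11
SsWRKY77	willow_GLEAN_10005468	17	IIe	27	96	411	5.96	45.7	2
SsWRKY78	willow_GLEAN_10006860	18	I	–	90	1593	8.67	179.0	10
SsWRKY79	willow_GLEAN_10006862	18	IIa	18/60	9	320	8.57	35.6	4
SsWRKY80	willow_GLEAN_10011608	18	I	32	–	528	5.74	57.8	4
SsWRKY81	willow_GLEAN_10004546	18	IId	7	7,91	300	9.80	32.8	2
SsWRKY82	willow_GLEAN_10003422	19	IId	11/17	24	339	9.58	37.1	2
SsWRKY83	willow_GLEAN_10011321	19	III	55	36,76	358	5.63	38.7	2
SsWRKY84	willow_GLEAN_10005288	19	I	33	4	597	6.69	65.6	4
SsWRKY85	willow_GLEAN_10002834	N/A	IIe	65	58	268	5.83	30.2	2
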