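case_id	age	n_patient_samples	n_control_samples	control_chromosomes_assessed	control_errors	expected_errors	expected_normal
1	26	3	16	336	7	1	62
2	29	7	69	2898	136	14	280
3	30	11	56	2352	62	12	450
4	30	5	56	2352	57	5	205
5	31	13	27	1134	21	10	536
6	31	9	27	1134	21	7	371
7	31	3	27	1134	20	2	124
8	31	2	27	1134	21	2	82
9	32	4	87	3654	169	8	160
10	32	5	87	3654	166	10	200
11	32	7	48	2016	31	5	289
12	33	2	93	3906	144	3	81
13	33	8	93	3720	140	12	308
14	33	9	48	2016	27	5	373
15	34	11	85	3570	44	6	456
16	34	3	167	7014	383	7	119
17	34	7	167	7014	383	16	278
18	34	3	167	7014	380	7	119
19	34	5	85	3570	46	3	207
20	35	2	144	6048	336	5	79
21	35	5	144	6048	337	12	198
22	35	3	144	6048	291	6	120
23	35	7	144	6048	293	14	280
24	35	5	63	2646	42	3	207
25	35	4	63	2646	42	3	165
26	36	3	86	3784	76	3	129
27	36	3	120	5040	286	7	119
28	36	2	120	5040	282	5	79
29	36	4	120	5040	277	9	159
30	36	5	120	5040	282	12	198
31	36	8	120	5040	282	19	317
32	36	2	86	3612	73	2	82
33	36	4	47	987	44	4	80
34	37	6	122	5124	289	14	238
35	37	5	122	5124	290	12	198
36	37	9	122	5124	276	20	358
37	37	6	122	5124	277	14	238
38	38	2	98	4116	321	7	77
39	39	8	108	4536	227	17	319
40	39	2	108	4536	240	4	80
41	40	7	236	9912	484	14	280
42	40	3	236	9912	500	6	120
43	41	3	120	5040	129	3	123
44	41	5	120	5040	126	5	205
45	42	9	65	1365	148	20	169
46	42	8	65	1365	148	18	150
47	42	3	76	3192	75	3	123
48	42	5	123	5166	388	16	194
49	43	7	61	1342	137	16	138
50	43	2	46	2024	96	4	84
51	36	4	47	987	44	4	80
52	36	3	47	987	44	3	60
53	26	3	16	336	8	2	61
54	42	9	65	1365	150	21	168
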