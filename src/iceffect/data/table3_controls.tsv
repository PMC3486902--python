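matched_case_id	age	stage	n_patients	n_samples	chromosomes_assessed	errors
1	26	PB	2	16	336	7
2	29	Bla	7	69	2898	136
3	30	Bla	5	56	2352	62
4	30	Bla	5	56	2352	57
5	31	TE	4	27	1134	21
6	31	TE	4	27	1134	21
7	31	TE	4	27	1134	20
8	31	TE	4	27	1134	21
9	32	Bla	10	87	3654	169
10	32	Bla	10	87	3654	166
11	32	TE	5	48	2016	31
12	33	Bla	10	93	3906	144
13	33	Bla	10	93	3720	140
14	33	TE	9	48	2016	27
15	34	TE	13	85	3570	44
16	34	Bla	18	167	7014	383
17	34	Bla	18	167	7014	383
18	34	Bla	18	167	7014	380
19	34	TE	13	85	3570	46
20	35	Bla	17	144	6048	336
21	35	Bla	17	144	6048	337
22	35	Bla	17	144	6048	291
23	35	Bla	17	144	6048	293
24	35	TE	8	63	2646	42
25	35	TE	8	63	2646	42
26	36	TE	13	86	3784	76
27	36	Bla	14	120	5040	286
28	36	Bla	14	120	5040	282
29	36	Bla	14	120	5040	277
30	36	Bla	14	120	5040	282
31	36	Bla	14	120	5040	282
32	36	TE	13	86	3612	73
33	36	PB	7	47	987	44
34	37	Bla	17	122	5124	289
35	37	Bla	17	122	5124	277
36	37	Bla	17	122	5124	290
37	37	Bla	17	122	5124	276
38	38	Bla	16	98	4116	321
39	39	Bla	16	108	4536	227
40	39	Bla	16	108	4536	240
41	40	Bla	16	236	9912	484
42	40	Bla	16	236	9912	500
43	41	TE	21	120	5040	129
44	41	TE	21	120	5040	126
45	42	PB	12	65	1365	148
46	42	PB	12	65	1365	148
47	42	TE	16	76	3192	75
48	42	Bla	17	123	5166	388
49	43	PB	10	61	1342	137
50	43	TE	11	46	2024	96
51	36	PB	7	47	987	44
52	36	PB	7	47	987	44
53	26	PB	2	16	336	8
54	42	PB	12	65	1365	150
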