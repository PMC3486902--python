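case_id	patient_id	maternal_age	rearrangement_class	stage	n_samples	chromosomes_assessed	errors
1	1	26	Rec	PB	3	63	1
2	2	29	Rec	Bla	7	294	7
3	2	30	Rec	Bla	11	462	6
4	3	30	Rec	Bla	5	210	17
5	4	31	Rob	TE	13	546	9
6	4	31	Rob	TE	9	378	2
7	5	31	Rec	TE	3	126	0
8	6	31	Rob	TE	2	84	4
9	7	32	Rob	Bla	4	168	10
10	5	32	Rec	Bla	5	210	13
11	8	32	Rec	TE	7	294	13
12	9	33	Rob	Bla	2	84	4
13	10	33	Rec/Inv	Bla	8	320	37
14	11	33	Rec	TE	9	378	2
15	12	34	Rob	TE	11	462	7
16	13	34	Rec	Bla	3	126	2
17	14	34	Rob	Bla	7	294	22
18	15	34	Rec	Bla	3	126	1
19	16	34	Rec	TE	5	210	3
20	17	35	Rec	Bla	2	84	2
21	18	35	Rec	Bla	5	210	5
22	19	35	Rec	Bla	3	126	24
23	20	35	Rob	Bla	7	294	23
24	21	35	Rec	TE	5	210	1
25	21	35	Rec	TE	4	168	2
26	22	36	Inv	TE	3	132	1
27	23	36	Rec	Bla	3	126	4
28	24	36	Rob	Bla	2	84	10
29	25	36	Rec	Bla	4	168	3
30	26	36	Rob	Bla	5	210	18
31	27	36	Rob	Bla	8	336	43
32	19	36	Rec	TE	2	84	0
33	28	36	Rob	PB	4	84	3
34	29	37	Rob	Bla	6	252	22
35	29	37	Rob	Bla	5	210	5
36	30	37	Rec	Bla	9	378	29
37	31	37	Rob	Bla	6	252	29
38	32	38	Rob	Bla	2	84	2
39	33	39	Rob	Bla	8	336	27
40	34	39	Rec	Bla	2	84	4
41	35	40	Rec	Bla	7	294	10
42	36	40	Rec	Bla	3	126	3
43	37	41	Rec	TE	3	126	4
44	38	41	Rob	TE	5	210	17
45	39	42	Rob	PB	9	189	17
46	39	42	Rob	PB	8	168	16
47	39	42	Rob	TE	3	126	4
48	40	42	Rec	Bla	5	210	22
49	41	43	Inv	PB	7	154	12
50	41	43	Inv	TE	2	88	2
51	42	36	Rob	PB	4	84	3
52	42	36	Rob	PB	3	63	8
53	43	26	Rec	PB	3	63	0
54	44	42	Rob	PB	9	189	18
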