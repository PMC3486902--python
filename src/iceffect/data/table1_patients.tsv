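patient_id	karyotype	stages_tested
1	46,XX,t(9;16)(p13.1;p11.2)	PB
2	46,XY,t(17;19)(q25.3;q13.1)	Bla/Bla
3	46,XY,t(16;17)(q11;p13.3)	Bla
4	45,XY,der(13;14)(q10;q10)	TE/TE
5	46,XY,t(1;2)(q23.1;q35)	Bla/TE
6	45,XY,der(14;21)(q10;q10)	TE
7	45,XY,der(13;14)(q10;q10)	Bla
8	46,XY,t(1;3)(q31;p13)	TE
9	45,XY,der(14;21)(q10;q10)	Bla
10	46,XY,t(5;15)(q13.1;q21.2)/46,XX,inv(3)(q25.1;q26.2)	Bla
11	46,XY,t(11;22)(q23;q11.2)	TE
12	45,XY,der(13;15)(q10;q10)	TE
13	46,XY,t(13;15)(q21.3;q11.2)	Bla
14	45,XX,der(13;15)(q10;q10)	Bla
15	46,XX,t(17;18)(p11.2;p11.2)	Bla
16	46,XX,t(8;9)(p12;q31)	TE
17	46,XY,t(1;8)(q25.3;p11.2)	Bla
18	46,XX,t(10;16)(q11.2;p11.2)	Bla
19	46,XX,t(1;2)(q24;p21)	Bla/TE
20	45,XY,der(13;14)(q10;q10)	Bla
21	46,XX,t(1;5)(p36.1;q33)	TE/TE
22	46,XY,inv(8)(p21q24.1)	TE
23	46,XY,t(10;17)(q21.2;p11.2)	Bla
24	45,XY,der(13;14)(q10;q10)	Bla
25	46,XY,t(7;18)(p15.3;q12.2)	Bla
26	45,XY,der(13;14)(q10;q10)	Bla
27	45,XX,der(13;14)(q10;q10)	Bla
28	45,XX,der(13;14)(q10;q10)	PB
29	45,XX,der(13;21)(q10;q10)	Bla/Bla
30	46,XY,t(1;3)(q31;p13)	Bla
31	45,XX,der(13;14)(q10;q10)	Bla
32	45,XY,der(14;21)(q10;q10)	Bla
33	45,XY,der(14;21)(q10;q10)	Bla
34	46,XY,t(17;21)(q21;q22)	Bla
35	46,XY,t(1;15)(q21p11.2)	Bla
36	46,XX,t(7;10)(p11.2;p11.23)	Bla
37	46,XY,t(5;7)(q23.2;p14)	TE
38	45,XX,der(13;14)(q10;q10)	TE
39	45,XX,der(13;14)(q10;q10)	PB/PB/TE
40	46,XX,t(4;11)(q24;q11)	Bla
41	46,XX,inv(5)(p13.1-q13.3)	PB/TE
42	45,XX,der(13;14)(q10;q10)	PB/PB
43	46,XX,t(9;16)(p13.1;p11.2)	PB
44	45,XX,der(13;21)(q10;q10)	PB
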