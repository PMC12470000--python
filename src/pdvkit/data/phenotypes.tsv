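subject_id	sex	age_years	id_moderate_or_worse	nonverbal	epilepsy	regression	tics
1	male	4	yes	no	no	no	no
2	male	6	yes	no	no	no	no
3	male	7	yes	no	no	no	no
4	male	8	yes	no	no	no	no
5	male	9	yes	no	no	no	no
6	male	9	yes	no	no	no	no
7	male	10	yes	no	no	no	no
8	male	11	yes	no	no	no	no
9	male	12	yes	yes	no	no	no
10	male	19	yes	no	no	no	no
11	male	4	yes	no	no	no	no
12	male	6	yes	yes	no	no	no
13	male	7	yes	yes	no	no	no
14	male	8	yes	yes	no	no	no
15	male	9	yes	yes	no	no	no
16	male	9	yes	yes	no	no	no
17	male	10	yes	yes	no	no	no
18	male	11	yes	yes	no	no	no
19	male	12	yes	yes	no	no	no
20	male	14	yes	yes	no	no	no
21	male	4	yes	yes	no	yes	no
22	male	6	yes	yes	no	yes	no
23	male	7	yes	yes	no	no	no
24	male	8	yes	yes	no	yes	no
25	male	9	yes	yes	no	yes	no
26	male	9	yes	yes	no	no	no
27	male	10	yes	yes	no	yes	no
28	male	11	yes	yes	no	no	no
29	male	12	yes	yes	no	no	no
30	male	14	yes	yes	yes	no	no
31	male	4	yes	yes	no	yes	no
32	male	6	yes	yes	no	yes	no
33	male	7	yes	yes	no	yes	no
34	male	8	yes	yes	no	yes	no
35	male	9	yes	no	yes	no	no
36	male	9	yes	no	yes	no	no
37	male	10	yes	yes	no	yes	no
38	male	11	yes	no	yes	no	no
39	male	12	yes	yes	yes	yes	no
40	male	27	yes	yes	yes	yes	no
41	male	4	yes	yes	yes	yes	no
42	male	6	yes	no	yes	no	no
43	male	7	yes	no	yes	no	no
44	male	8	yes	yes	yes	yes	no
45	male	9	yes	no	yes	no	no
46	male	9	yes	no	yes	yes	no
47	male	10	yes	no	yes	no	no
48	male	11	yes	no	yes	yes	no
49	male	12	yes	no	yes	yes	no
50	male	14	yes	no	yes	yes	no
51	female	4	yes	no	yes	yes	no
52	female	6	yes	no	yes	yes	no
53	male	7	yes	no	yes	yes	no
54	female	8	yes	no	yes	yes	no
55	male	9	yes	no	yes	yes	no
56	male	9	yes	no	yes	yes	no
57	male	10	yes	no	yes	yes	no
58	male	11	yes	no	yes	yes	no
59	male	12	yes	no	no	yes	no
60	male	14	yes	no	no	yes	no
61	female	4	yes	no	yes	yes	no
62	female	6	yes	no	yes	yes	no
63	female	7	yes	no	yes	yes	no
64	female	8	yes	no	yes	yes	no
65	male	9	yes	no	no	yes	no
66	female	9	yes	no	yes	yes	no
67	female	10	yes	no	no	yes	no
68	female	11	yes	no	yes	yes	no
69	female	12	yes	no	no	yes	no
70	female	40	yes	no	no	yes	no
71	female	4	yes	no	yes	yes	no
72	female	6	yes	no	no	yes	yes
73	male	7	yes	no	no	yes	yes
74	male	8	yes	no	no	yes	yes
75	female	9	yes	no	no	yes	no
76	female	9	yes	no	no	yes	no
77	male	10	yes	no	no	yes	yes
78	female	11	yes	no	no	yes	no
79	female	12	yes	no	no	yes	yes
80	female	14	no	no	no	yes	yes
81	female	4	no	no	no	yes	yes
82	male	6	no	no	no	yes	yes
83	male	7	yes	no	no	yes	yes
84	male	8	no	no	no	yes	no
85	male	9	no	no	no	yes	no
86	male	9	no	no	no	yes	no
87	male	10	yes	no	no	yes	no
88	male	11	no	no	no	yes	no
89	male	12	yes	no	no	yes	no
90	male	14	no	no	no	yes	no
91	male	4	yes	no	no	yes	no
92	male	6	unknown	no	no	yes	no
93	male	7	yes	no	no	no	no
94	male	8	yes	no	no	no	no
95	male	9	unknown	no	no	no	no
96	male	9	no	no	no	no	no
97	male	10	no	no	no	no	no
98	male	11	unknown	no	no	no	no
99	male	12	unknown	no	no	no	no
100	male	14	unknown	no	no	no	no
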