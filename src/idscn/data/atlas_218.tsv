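region_id	name	hemisphere	homotopic_partner_id	subnet
1	L.AN-1	left	2	AN
2	R.AN-1	right	1	AN
3	L.CN-2	left	4	CN
4	R.CN-2	right	3	CN
5	L.DMN-3	left	6	DMN
6	R.DMN-3	right	5	DMN
7	L.DAN-4	left	8	DAN
8	R.DAN-4	right	7	DAN
9	L.LN-5	left	10	LN
10	R.LN-5	right	9	LN
11	L.SMN-6	left	12	SMN
12	R.SMN-6	right	11	SMN
13	L.VAN-7	left	14	VAN
14	R.VAN-7	right	13	VAN
15	L.VN-8	left	16	VN
16	R.VN-8	right	15	VN
17	L.AN-9	left	18	AN
18	R.AN-9	right	17	AN
19	L.CN-10	left	20	CN
20	R.CN-10	right	19	CN
21	L.DMN-11	left	22	DMN
22	R.DMN-11	right	21	DMN
23	L.DAN-12	left	24	DAN
24	R.DAN-12	right	23	DAN
25	L.LN-13	left	26	LN
26	R.LN-13	right	25	LN
27	L.SMN-14	left	28	SMN
28	R.SMN-14	right	27	SMN
29	L.VAN-15	left	30	VAN
30	R.VAN-15	right	29	VAN
31	L.VN-16	left	32	VN
32	R.VN-16	right	31	VN
33	L.AN-17	left	34	AN
34	R.AN-17	right	33	AN
35	L.CN-18	left	36	CN
36	R.CN-18	right	35	CN
37	L.DMN-19	left	38	DMN
38	R.DMN-19	right	37	DMN
39	L.DAN-20	left	40	DAN
40	R.DAN-20	right	39	DAN
41	L.LN-21	left	42	LN
42	R.LN-21	right	41	LN
43	L.SMN-22	left	44	SMN
44	R.SMN-22	right	43	SMN
45	L.VAN-23	left	46	VAN
46	R.VAN-23	right	45	VAN
47	L.VN-24	left	48	VN
48	R.VN-24	right	47	VN
49	L.AN-25	left	50	AN
50	R.AN-25	right	49	AN
51	L.CN-26	left	52	CN
52	R.CN-26	right	51	CN
53	L.DMN-27	left	54	DMN
54	R.DMN-27	right	53	DMN
55	L.DAN-28	left	56	DAN
56	R.DAN-28	right	55	DAN
57	L.LN-29	left	58	LN
58	R.LN-29	right	57	LN
59	L.SMN-30	left	60	SMN
60	R.SMN-30	right	59	SMN
61	L.VAN-31	left	62	VAN
62	R.VAN-31	right	61	VAN
63	L.VN-32	left	64	VN
64	R.VN-32	right	63	VN
65	L.AN-33	left	66	AN
66	R.AN-33	right	65	AN
67	L.CN-34	left	68	CN
68	R.CN-34	right	67	CN
69	L.DMN-35	left	70	DMN
70	R.DMN-35	right	69	DMN
71	L.DAN-36	left	72	DAN
72	R.DAN-36	right	71	DAN
73	L.LN-37	left	74	LN
74	R.LN-37	right	73	LN
75	L.SMN-38	left	76	SMN
76	R.SMN-38	right	75	SMN
77	L.VAN-39	left	78	VAN
78	R.VAN-39	right	77	VAN
79	L.VN-40	left	80	VN
80	R.VN-40	right	79	VN
81	L.AN-41	left	82	AN
82	R.AN-41	right	81	AN
83	L.CN-42	left	84	CN
84	R.CN-42	right	83	CN
85	L.DMN-43	left	86	DMN
86	R.DMN-43	right	85	DMN
87	L.DAN-44	left	88	DAN
88	R.DAN-44	right	87	DAN
89	L.LN-45	left	90	LN
90	R.LN-45	right	89	LN
91	L.SMN-46	left	92	SMN
92	R.SMN-46	right	91	SMN
93	L.VAN-47	left	94	VAN
94	R.VAN-47	right	93	VAN
95	L.VN-48	left	96	VN
96	R.VN-48	right	95	VN
97	L.AN-49	left	98	AN
98	R.AN-49	right	97	AN
99	L.CN-50	left	100	CN
100	R.CN-50	right	99	CN
101	L.DMN-51	left	102	DMN
102	R.DMN-51	right	101	DMN
103	L.DAN-52	left	104	DAN
104	R.DAN-52	right	103	DAN
105	L.LN-53	left	106	LN
106	R.LN-53	right	105	LN
107	L.SMN-54	left	108	SMN
108	R.SMN-54	right	107	SMN
109	L.VAN-55	left	110	VAN
110	R.VAN-55	right	109	VAN
111	L.VN-56	left	112	VN
112	R.VN-56	right	111	VN
113	L.AN-57	left	114	AN
114	R.AN-57	right	113	AN
115	L.CN-58	left	116	CN
116	R.CN-58	right	115	CN
117	L.DMN-59	left	118	DMN
118	R.DMN-59	right	117	DMN
119	L.DAN-60	left	120	DAN
120	R.DAN-60	right	119	DAN
121	L.LN-61	left	122	LN
122	R.LN-61	right	121	LN
123	L.SMN-62	left	124	SMN
124	R.SMN-62	right	123	SMN
125	L.VAN-63	left	126	VAN
126	R.VAN-63	right	125	VAN
127	L.VN-64	left	128	VN
128	R.VN-64	right	127	VN
129	L.AN-65	left	130	AN
130	R.AN-65	right	129	AN
131	L.CN-66	left	132	CN
132	R.CN-66	right	131	CN
133	L.DMN-67	left	134	DMN
134	R.DMN-67	right	133	DMN
135	L.DAN-68	left	136	DAN
136	R.DAN-68	right	135	DAN
137	L.LN-69	left	138	LN
138	R.LN-69	right	137	LN
139	L.SMN-70	left	140	SMN
140	R.SMN-70	right	139	SMN
141	L.VAN-71	left	142	VAN
142	R.VAN-71	right	141	VAN
143	L.VN-72	left	144	VN
144	R.VN-72	right	143	VN
145	L.AN-73	left	146	AN
146	R.AN-73	right	145	AN
147	L.CN-74	left	148	CN
148	R.CN-74	right	147	CN
149	L.DMN-75	left	150	DMN
150	R.DMN-75	right	149	DMN
151	L.DAN-76	left	152	DAN
152	R.DAN-76	right	151	DAN
153	L.LN-77	left	154	LN
154	R.LN-77	right	153	LN
155	L.SMN-78	left	156	SMN
156	R.SMN-78	right	155	SMN
157	L.VAN-79	left	158	VAN
158	R.VAN-79	right	157	VAN
159	L.VN-80	left	160	VN
160	R.VN-80	right	159	VN
161	L.AN-81	left	162	AN
162	R.AN-81	right	161	AN
163	L.CN-82	left	164	CN
164	R.CN-82	right	163	CN
165	L.DMN-83	left	166	DMN
166	R.DMN-83	right	165	DMN
167	L.DAN-84	left	168	DAN
168	R.DAN-84	right	167	DAN
169	L.LN-85	left	170	LN
170	R.LN-85	right	169	LN
171	L.SMN-86	left	172	SMN
172	R.SMN-86	right	171	SMN
173	L.VAN-87	left	174	VAN
174	R.VAN-87	right	173	VAN
175	L.VN-88	left	176	VN
176	R.VN-88	right	175	VN
177	L.AN-89	left	178	AN
178	R.AN-89	right	177	AN
179	L.CN-90	left	180	CN
180	R.CN-90	right	179	CN
181	L.DMN-91	left	182	DMN
182	R.DMN-91	right	181	DMN
183	L.DAN-92	left	184	DAN
184	R.DAN-92	right	183	DAN
185	L.LN-93	left	186	LN
186	R.LN-93	right	185	LN
187	L.SMN-94	left	188	SMN
188	R.SMN-94	right	187	SMN
189	L.VAN-95	left	190	VAN
190	R.VAN-95	right	189	VAN
191	L.VN-96	left	192	VN
192	R.VN-96	right	191	VN
193	L.AN-97	left	194	AN
194	R.AN-97	right	193	AN
195	L.CN-98	left	196	CN
196	R.CN-98	right	195	CN
197	L.DMN-99	left	198	DMN
198	R.DMN-99	right	197	DMN
199	L.DAN-100	left	200	DAN
200	R.DAN-100	right	199	DAN
201	L.LN-101	left	202	LN
202	R.LN-101	right	201	LN
203	L.SMN-102	left	204	SMN
204	R.SMN-102	right	203	SMN
205	L.VAN-103	left	206	VAN
206	R.VAN-103	right	205	VAN
207	L.VN-104	left	208	VN
208	R.VN-104	right	207	VN
209	L.AN-105	left	210	AN
210	R.AN-105	right	209	AN
211	L.CN-106	left	212	CN
212	R.CN-106	right	211	CN
213	L.DMN-107	left	214	DMN
214	R.DMN-107	right	213	DMN
215	L.DAN-108	left	216	DAN
216	R.DAN-108	right	215	DAN
217	L.LN-109	left	218	LN
218	R.LN-109	right	217	LN
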