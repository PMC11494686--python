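index	label	hemisphere	group
1	V1	L	early visual
2	MST	L	ventrolateral visual
3	V6	L	dorsal visual
4	V2	L	early visual
5	V3	L	early visual
6	V4	L	early visual
7	V8	L	ventrolateral visual
8	4	L	other
9	3b	L	other
10	FEF	L	other
11	PEF	L	other
12	55b	L	other
13	V3A	L	dorsal visual
14	RSC	L	other
15	POS2	L	other
16	V7	L	dorsal visual
17	IPS1	L	dorsal visual
18	FFC	L	ventrolateral visual
19	V3B	L	dorsal visual
20	LO1	L	ventrolateral visual
21	LO2	L	ventrolateral visual
22	PIT	L	ventrolateral visual
23	MT	L	ventrolateral visual
24	A1	L	other
25	PSL	L	temporal semantic
26	SFL	L	other
27	PCV	L	other
28	STV	L	other
29	7Pm	L	other
30	7m	L	other
31	POS1	L	other
32	23d	L	other
33	v23ab	L	other
34	d23ab	L	other
35	31pv	L	other
36	5m	L	other
37	5mv	L	other
38	23c	L	other
39	5L	L	other
40	24dd	L	other
41	24dv	L	other
42	7AL	L	other
43	SCEF	L	other
44	6ma	L	other
45	7Am	L	other
46	7PL	L	other
47	7PC	L	other
48	LIPv	L	intraparietal
49	VIP	L	intraparietal
50	MIP	L	intraparietal
51	1	L	other
52	2	L	other
53	3a	L	other
54	6d	L	other
55	6mp	L	other
56	6v	L	other
57	p24pr	L	other
58	33pr	L	other
59	a24pr	L	other
60	p32pr	L	other
61	a24	L	reward vmPFC/OFC/ACC
62	d32	L	reward vmPFC/OFC/ACC
63	8BM	L	other
64	p32	L	reward vmPFC/OFC/ACC
65	10r	L	reward vmPFC/OFC/ACC
66	47m	L	reward vmPFC/OFC/ACC
67	8Av	L	other
68	8Ad	L	other
69	9m	L	other
70	8BL	L	other
71	9p	L	other
72	10d	L	reward vmPFC/OFC/ACC
73	8C	L	other
74	44	L	inferior frontal language
75	45	L	inferior frontal language
76	47l	L	inferior frontal language
77	a47r	L	other
78	6r	L	other
79	IFJa	L	inferior frontal language
80	IFJp	L	inferior frontal language
81	IFSp	L	inferior frontal language
82	IFSa	L	inferior frontal language
83	p9-46v	L	other
84	46	L	other
85	a9-46v	L	other
86	9-46d	L	other
87	9a	L	other
88	10v	L	reward vmPFC/OFC/ACC
89	a10p	L	reward vmPFC/OFC/ACC
90	10pp	L	reward vmPFC/OFC/ACC
91	11l	L	reward vmPFC/OFC/ACC
92	13l	L	reward vmPFC/OFC/ACC
93	OFC	L	reward vmPFC/OFC/ACC
94	47s	L	reward vmPFC/OFC/ACC
95	LIPd	L	intraparietal
96	6a	L	other
97	i6-8	L	other
98	s6-8	L	other
99	43	L	other
100	OP4	L	other
101	OP1	L	other
102	OP2-3	L	other
103	52	L	other
104	RI	L	other
105	PFcm	L	other
106	PoI2	L	other
107	TA2	L	other
108	FOP4	L	other
109	MI	L	other
110	Pir	L	other
111	AVI	L	other
112	AAIC	L	other
113	FOP1	L	other
114	FOP3	L	other
115	FOP2	L	other
116	PFt	L	other
117	AIP	L	intraparietal
118	EC	L	hippocampal system
119	PreS	L	hippocampal system
120	H	L	hippocampal system
121	ProS	L	hippocampal system
122	PeEc	L	hippocampal system
123	STGa	L	temporal semantic
124	PBelt	L	other
125	A5	L	other
126	PHA1	L	medial parahippocampal
127	PHA3	L	medial parahippocampal
128	STSda	L	temporal semantic
129	STSdp	L	temporal semantic
130	STSvp	L	temporal semantic
131	TGd	L	temporal semantic
132	TE1a	L	temporal semantic
133	TE1p	L	temporal semantic
134	TE2a	L	temporal semantic
135	TF	L	hippocampal system
136	TE2p	L	temporal semantic
137	PHT	L	ventrolateral visual
138	PH	L	ventrolateral visual
139	TPOJ1	L	other
140	TPOJ2	L	other
141	TPOJ3	L	other
142	DVT	L	dorsal visual
143	PGp	L	other
144	IP2	L	intraparietal
145	IP1	L	intraparietal
146	IP0	L	intraparietal
147	PFop	L	other
148	PF	L	other
149	PFm	L	other
150	PGi	L	other
151	PGs	L	other
152	V6A	L	dorsal visual
153	VMV1	L	ventromedial visual
154	VMV3	L	ventromedial visual
155	PHA2	L	medial parahippocampal
156	V4t	L	ventrolateral visual
157	FST	L	ventrolateral visual
158	V3CD	L	ventrolateral visual
159	LO3	L	ventrolateral visual
160	VMV2	L	ventromedial visual
161	31pd	L	other
162	31a	L	other
163	VVC	L	ventromedial visual
164	25	L	reward vmPFC/OFC/ACC
165	s32	L	reward vmPFC/OFC/ACC
166	pOFC	L	reward vmPFC/OFC/ACC
167	PoI1	L	other
168	Ig	L	other
169	FOP5	L	other
170	p10p	L	reward vmPFC/OFC/ACC
171	p47r	L	other
172	TGv	L	temporal semantic
173	MBelt	L	other
174	LBelt	L	other
175	A4	L	other
176	STSva	L	temporal semantic
177	TE1m	L	temporal semantic
178	PI	L	other
179	a32pr	L	other
180	p24	L	reward vmPFC/OFC/ACC
181	V1	R	early visual
182	MST	R	ventrolateral visual
183	V6	R	dorsal visual
184	V2	R	early visual
185	V3	R	early visual
186	V4	R	early visual
187	V8	R	ventrolateral visual
188	4	R	other
189	3b	R	other
190	FEF	R	other
191	PEF	R	other
192	55b	R	other
193	V3A	R	dorsal visual
194	RSC	R	other
195	POS2	R	other
196	V7	R	dorsal visual
197	IPS1	R	dorsal visual
198	FFC	R	ventrolateral visual
199	V3B	R	dorsal visual
200	LO1	R	ventrolateral visual
201	LO2	R	ventrolateral visual
202	PIT	R	ventrolateral visual
203	MT	R	ventrolateral visual
204	A1	R	other
205	PSL	R	temporal semantic
206	SFL	R	other
207	PCV	R	other
208	STV	R	other
209	7Pm	R	other
210	7m	R	other
211	POS1	R	other
212	23d	R	other
213	v23ab	R	other
214	d23ab	R	other
215	31pv	R	other
216	5m	R	other
217	5mv	R	other
218	23c	R	other
219	5L	R	other
220	24dd	R	other
221	24dv	R	other
222	7AL	R	other
223	SCEF	R	other
224	6ma	R	other
225	7Am	R	other
226	7PL	R	other
227	7PC	R	other
228	LIPv	R	intraparietal
229	VIP	R	intraparietal
230	MIP	R	intraparietal
231	1	R	other
232	2	R	other
233	3a	R	other
234	6d	R	other
235	6mp	R	other
236	6v	R	other
237	p24pr	R	other
238	33pr	R	other
239	a24pr	R	other
240	p32pr	R	other
241	a24	R	reward vmPFC/OFC/ACC
242	d32	R	reward vmPFC/OFC/ACC
243	8BM	R	other
244	p32	R	reward vmPFC/OFC/ACC
245	10r	R	reward vmPFC/OFC/ACC
246	47m	R	reward vmPFC/OFC/ACC
247	8Av	R	other
248	8Ad	R	other
249	9m	R	other
250	8BL	R	other
251	9p	R	other
252	10d	R	reward vmPFC/OFC/ACC
253	8C	R	other
254	44	R	inferior frontal language
255	45	R	inferior frontal language
256	47l	R	inferior frontal language
257	a47r	R	other
258	6r	R	other
259	IFJa	R	inferior frontal language
260	IFJp	R	inferior frontal language
261	IFSp	R	inferior frontal language
262	IFSa	R	inferior frontal language
263	p9-46v	R	other
264	46	R	other
265	a9-46v	R	other
266	9-46d	R	other
267	9a	R	other
268	10v	R	reward vmPFC/OFC/ACC
269	a10p	R	reward vmPFC/OFC/ACC
270	10pp	R	reward vmPFC/OFC/ACC
271	11l	R	reward vmPFC/OFC/ACC
272	13l	R	reward vmPFC/OFC/ACC
273	OFC	R	reward vmPFC/OFC/ACC
274	47s	R	reward vmPFC/OFC/ACC
275	LIPd	R	intraparietal
276	6a	R	other
277	i6-8	R	other
278	s6-8	R	other
279	43	R	other
280	OP4	R	other
281	OP1	R	other
282	OP2-3	R	other
283	52	R	other
284	RI	R	other
285	PFcm	R	other
286	PoI2	R	other
287	TA2	R	other
288	FOP4	R	other
289	MI	R	other
290	Pir	R	other
291	AVI	R	other
292	AAIC	R	other
293	FOP1	R	other
294	FOP3	R	other
295	FOP2	R	other
296	PFt	R	other
297	AIP	R	intraparietal
298	EC	R	hippocampal system
299	PreS	R	hippocampal system
300	H	R	hippocampal system
301	ProS	R	hippocampal system
302	PeEc	R	hippocampal system
303	STGa	R	temporal semantic
304	PBelt	R	other
305	A5	R	other
306	PHA1	R	medial parahippocampal
307	PHA3	R	medial parahippocampal
308	STSda	R	temporal semantic
309	STSdp	R	temporal semantic
310	STSvp	R	temporal semantic
311	TGd	R	temporal semantic
312	TE1a	R	temporal semantic
313	TE1p	R	temporal semantic
314	TE2a	R	temporal semantic
315	TF	R	hippocampal system
316	TE2p	R	temporal semantic
317	PHT	R	ventrolateral visual
318	PH	R	ventrolateral visual
319	TPOJ1	R	other
320	TPOJ2	R	other
321	TPOJ3	R	other
322	DVT	R	dorsal visual
323	PGp	R	other
324	IP2	R	intraparietal
325	IP1	R	intraparietal
326	IP0	R	intraparietal
327	PFop	R	other
328	PF	R	other
329	PFm	R	other
330	PGi	R	other
331	PGs	R	other
332	V6A	R	dorsal visual
333	VMV1	R	ventromedial visual
334	VMV3	R	ventromedial visual
335	PHA2	R	medial parahippocampal
336	V4t	R	ventrolateral visual
337	FST	R	ventrolateral visual
338	V3CD	R	ventrolateral visual
339	LO3	R	ventrolateral visual
340	VMV2	R	ventromedial visual
341	31pd	R	other
342	31a	R	other
343	VVC	R	ventromedial visual
344	25	R	reward vmPFC/OFC/ACC
345	s32	R	reward vmPFC/OFC/ACC
346	pOFC	R	reward vmPFC/OFC/ACC
347	PoI1	R	other
348	Ig	R	other
349	FOP5	R	other
350	p10p	R	reward vmPFC/OFC/ACC
351	p47r	R	other
352	TGv	R	temporal semantic
353	MBelt	R	other
354	LBelt	R	other
355	A4	R	other
356	STSva	R	temporal semantic
357	TE1m	R	temporal semantic
358	PI	R	other
359	a32pr	R	other
360	p24	R	reward vmPFC/OFC/ACC
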