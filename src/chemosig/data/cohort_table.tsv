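patient_id	age	cigarettes_per_day	alcohol_printed	hemoglobin	regimen	response	study	status
23	63	40	>1	12.1	PF	CCR	MA	A
40	45	50	<1	15.1	PF	CCR	MA/TLDA	A
57	44	40	>2	14.4	PF	CCR	MA/TLDA	A
109	60	40	1	13.3	PF	CCR	MA/TLDA	A
110	56	45	<1	12.8	PF	CCR	MA/TLDA	A
121	44	45	>2	12.8	PF	CCR	MA/TLDA	D
130	44	45	3	12.1	PF	CCR	MA/TLDA	D
156	56	40	>3	12.7	PF	CCR	MA/TLDA	D
157	71	0	0	11.1	PF	CCR	MA/TLDA	A
164	60	20	0	11.4	PF	CCR	MA/TLDA	A
169	58	65	1	12.7	PF	CCR	MA/TLDA	A
195	47	30	1	12.1	PF	CCR	MA/TLDA	A
219	52	40	1	12.1	PF	CCR	MA/TLDA	A
48	55	55	>2	11.1	PF	NR	MA/TLDA	D
140	50	10	1	12.1	PF	NR	MA/TLDA	A
143	62	20	1	13.1	PF	NR	MA/TLDA	A
159	58	10	1	12.1	PF	NR	MA/TLDA	A
198	63	20	1	12.1	PF	NR	MA/TLDA	D
210	59	10	2	11.4	PF	NR	MA/TLDA	A
223	65	40	2	11.9	PF	NR	MA/TLDA	D
246	66	30	2	12.9	PF	NR	MA/TLDA	D
302	69	40	>2	12.1	PF	NR	MA/TLDA	D
303	58	20	>2	12.9	PF	NR	MA/TLDA	A
27	50	20	>2	12.8	PF	NR	TLDA	D
39	43	15	1	12.1	PF	NR	TLDA	A
76	48	0	<1	14.1	PF	NR	TLDA	D
318	62	60	>2	11.1	PF	NR	TLDA	D
329	49	40	>1	12.2	PF	NR	TLDA	A
310	58	90	>2	11.2	T1PF	CCR	TLDA	A
323	45	10	<1	12.5	T1PF	CCR	TLDA	A
353	52	25	>1	11.5	T1PF	CCR	TLDA	D
374	62	35	>1	12	T1PF	CCR	TLDA	D
138	54	20	1	11.2	T1PF	NR	TLDA	A
162	58	25	>2	10.8	T1PF	NR	TLDA	D
174	47	30	1	11.5	T1PF	NR	TLDA	D
350	69	30	1	11.6	T1PF	NR	TLDA	D
387	53	20	1	11.5	T2PF	CCR	TLDA	A
395	61	10	1	12.1	T2PF	CCR	TLDA	A
413	64	10	1	11.5	T2PF	CCR	TLDA	A
416	62	20	1	12.1	T2PF	CCR	TLDA	A
417	65	15	2	12.1	T2PF	CCR	TLDA	A
419	51	10	0	12.1	T2PF	CCR	TLDA	A
213	50	40	3	12	T2PF	NR	TLDA	D
427	55	20	1	11.5	T2PF	NR	TLDA	A
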