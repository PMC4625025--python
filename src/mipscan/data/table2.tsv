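name	length_aa	mw_kda	pi	tm	loc_wolf_psort	loc_plant_mploc	H2	H5	LE1	LE2	NPA_LB	NPA_LE	P1	P2	P3	P4	P5
RcPIP1;1	288	30.77	7.00	6	Plas	Plas	F	H	T	R	NPA	NPA	E	S	A	F	W
RcPIP1;2	287	30.69	7.69	6	Plas	Plas	F	H	T	R	NPA	NPA	E	S	A	F	W
RcPIP1;3	288	30.78	7.65	6	Plas	Plas	F	H	T	R	NPA	NPA	E	S	A	F	W
RcPIP1;4	287	30.67	8.30	6	Plas	Plas	F	H	T	R	NPA	NPA	E	S	A	F	W
RcPIP1;5	286	30.71	8.83	6	Plas	Plas	F	H	T	R	NPA	NPA	Q	S	A	F	W
RcPIP2;1	288	30.66	8.21	6	Plas	Plas	F	H	T	R	NPA	NPA	Q	S	A	F	W
RcPIP2;2	283	30.30	8.29	6	Plas	Plas	F	H	T	R	NPA	NPA	Q	S	A	F	W
RcPIP2;3	287	30.60	7.62	6	Plas	Plas	F	H	T	R	NPA	NPA	Q	S	A	F	W
RcPIP2;4	280	29.71	8.99	6	Plas	Plas	F	H	T	R	NPA	NPA	M	S	A	F	W
RcPIP2;5	270	28.56	6.29	6	Plas	Plas	F	H	T	R	NPA	NPA	M	S	A	F	W
RcTIP1;1	251	25.90	5.91	6	Vacu	Vacu	H	I	A	V	NPA	NPA	T	S	A	Y	W
RcTIP1;2	252	25.92	5.35	6	Vacu	Vacu	H	I	A	V	NPA	NPA	T	S	A	Y	W
RcTIP1;3	252	25.80	4.94	6	Vacu	Vacu	H	I	A	V	NPA	NPA	T	S	A	Y	W
RcTIP1;4	252	26.26	5.13	6	Vacu	Vacu	H	I	A	V	NPA	NPA	T	S	A	Y	W
RcTIP2;1	248	25.03	5.06	6	Vacu	Vacu	H	I	G	R	NPA	NPA	T	S	A	Y	W
RcTIP2;2	250	25.22	4.93	6	Vacu	Vacu	H	I	G	R	NPA	NPA	T	S	A	Y	W
RcTIP3;1	255	27.11	6.49	6	Cyto	Vacu	H	I	A	R	NPA	NPA	T	A	A	Y	W
RcTIP4;1	247	26.15	6.12	6	Cyto	Vacu	H	I	A	R	NPA	NPA	T	S	A	Y	W
RcTIP5;1	252	25.92	6.71	6	Vacu	Vacu	N	V	G	C	NPA	NPA	A	A	A	Y	W
RcNIP1;1	271	28.86	9.26	6	Plas	Plas	W	V	A	R	NPA	NPA	F	S	A	Y	I
RcNIP2;1	297	31.49	9.02	6	Plas	Plas	G	S	G	R	NPA	NPA	L	T	A	Y	I
RcNIP3;1	282	30.65	6.21	6	Plas	Plas	W	A	A	R	NPA	NPA	F	S	A	F	I
RcNIP4;1	269	28.94	8.59	6	Plas	Plas	W	V	A	R	NPA	NPA	F	T	A	Y	M
RcNIP4;2	252	26.39	8.44	6	Plas	Plas	W	V	A	R	NPA	NPA	V	S	A	Y	I
RcNIP5;1	298	30.95	8.88	6	Plas	Plas	A	I	G	R	NPS	NPV	F	T	P	Y	L
RcNIP6;1	308	31.85	8.60	6	Plas	Plas	T	I	A	R	NPS	NPV	F	T	A	Y	L
RcNIP7;1	298	31.57	8.54	6	Plas	Plas	A	V	G	R	NPA	NPA	Y	S	A	Y	I
RcXIP1;1	309	33.22	6.92	6	Cyto	Plas	V	F	V	R	SPT	NPA	M	C	A	F	W
RcXIP1;2	303	32.55	6.91	6	Chlo	Plas	V	F	V	R	SPT	NPA	M	C	A	F	W
RcXIP1;3	285	30.80	7.94	6	Plas	Plas	V	F	V	R	SPA	NPA	M	C	V	F	W
RcXIP1;4	208	22.49	7.57	4	Pero	Plas	V	-	-	-	SPV	-	M	-	-	-	-
RcXIP2;1	306	32.22	8.22	6	Plas	Plas	I	F	V	R	NPV	NPA	V	C	A	F	W
RcXIP3;1	304	32.36	8.21	6	Plas	Plas	V	Y	A	R	NPI	NPA	V	C	A	F	W
RcSIP1;1	239	25.92	9.63	6	Plas	Plas	V	V	P	N	NPT	NPA	E	A	A	Y	W
RcSIP1;2	234	25.24	9.97	6	Vacu	Plas/Vacu	A	A	T	N	NPN	NPA	Q	A	A	Y	W
RcSIP1;3	239	25.62	9.74	6	Plas	Plas/Vacu	A	A	P	N	NPA	NPA	Q	V	A	Y	W
RcSIP2;1	240	26.05	9.82	6	Chlo	Plas/Vacu	S	H	G	S	NPL	NPA	I	V	A	Y	W
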