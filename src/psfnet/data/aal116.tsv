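index	name	abbreviation	division
1	Precental gyrus	PreCG	cerebrum
2	Precental gyrus	PreCG	cerebrum
3	Superior frontal gyrus, dorsolateral	SFGdor	cerebrum
4	Superior frontal gyrus, dorsolateral	SFGdor	cerebrum
5	Superior frontal gyrus, orbital part	ORBsup	cerebrum
6	Superior frontal gyrus, orbital part	ORBsup	cerebrum
7	Middle frontal gyrus	MFG	cerebrum
8	Middle frontal gyrus	MFG	cerebrum
9	Middle frontal gyrus, orbital part	ORBmid	cerebrum
10	Middle frontal gyrus, orbital part	ORBmid	cerebrum
11	Inferior frontal gyrus, opercular part	IFGoperc	cerebrum
12	Inferior frontal gyrus, opercular part	IFGoperc	cerebrum
13	Inferior frontal gyrus, triangular part	FGtriang	cerebrum
14	Inferior frontal gyrus, triangular part	FGtriang	cerebrum
15	Inferior frontal gyrus, orbital part	ORBinf	cerebrum
16	Inferior frontal gyrus, orbital part	ORBinf	cerebrum
17	Rolandic operculum	ROL	cerebrum
18	Rolandic operculum	ROL	cerebrum
19	Supplementary motor area	SMA	cerebrum
20	Supplementary motor area	SMA	cerebrum
21	Olfactory cortex	OLF	cerebrum
22	Olfactory cortex	OLF	cerebrum
23	Superior frontal gyrus, medial	SFGmed	cerebrum
24	Superior frontal gyrus, medial	SFGmed	cerebrum
25	Superior frontal gyrus, medial orbital	ORBsupmed	cerebrum
26	Superior frontal gyrus, medial orbital	ORBsupmed	cerebrum
27	Gyrus rectus	REC	cerebrum
28	Gyrus rectus	REC	cerebrum
29	Insula	Ins	cerebrum
30	Insula	Ins	cerebrum
31	Anterior cingulate and paracingulate gyri	ACG	cerebrum
32	Anterior cingulate and paracingulate gyri	ACG	cerebrum
33	Median cingulate and paracingulate gyri	DCG	cerebrum
34	Median cingulate and paracingulate gyri	DCG	cerebrum
35	Posterior cingulate gyrus	PCG	cerebrum
36	Posterior cingulate gyrus	PCG	cerebrum
37	Hippocampus	HIP	cerebrum
38	Hippocampus	HIP	cerebrum
39	Parahippocampal gyrus	PHG	cerebrum
40	Parahippocampal gyrus	PHG	cerebrum
41	Amygdala	AMYG	cerebrum
42	Amygdala	AMYG	cerebrum
43	Calcarine fissure and surrounding cortex	CAL	cerebrum
44	Calcarine fissure and surrounding cortex	CAL	cerebrum
45	Cuneus	CUN	cerebrum
46	Cuneus	CUN	cerebrum
47	Lingual gyrus	LING	cerebrum
48	Lingual gyrus	LING	cerebrum
49	Superior occipital gyrus	SOG	cerebrum
50	Superior occipital gyrus	SOG	cerebrum
51	Middle occipital gyrus	MOG	cerebrum
52	Middle occipital gyrus	MOG	cerebrum
53	Inferior occipital gyrus	IOG	cerebrum
54	Inferior occipital gyrus	IOG	cerebrum
55	Fusiform gyrus	FFG	cerebrum
56	Fusiform gyrus	FFG	cerebrum
57	Postcentral gyrus	PoCG	cerebrum
58	Postcentral gyrus	PoCG	cerebrum
59	Superior parietal gyrus	SPG	cerebrum
60	Superior parietal gyrus	SPG	cerebrum
61	Inferior parietal, but supramarginal and angular gyri	IPL	cerebrum
62	Inferior parietal, but supramarginal and angular gyri	IPL	cerebrum
63	Supramarginal gyrus	SMG	cerebrum
64	Supramarginal gyrus	SMG	cerebrum
65	Angular gyrus	ANG	cerebrum
66	Angular gyrus	ANG	cerebrum
67	Precuneus	PCUN	cerebrum
68	Precuneus	PCUN	cerebrum
69	Paracentral lobule	PCL	cerebrum
70	Paracentral lobule	PCL	cerebrum
71	Caudate nucleus	CAU	cerebrum
72	Caudate nucleus	CAU	cerebrum
73	Lenticular nucleus, putamen	PUT	cerebrum
74	Lenticular nucleus, putamen	PUT	cerebrum
75	Lenticular nucleus, pallidum	PAL	cerebrum
76	Lenticular nucleus, pallidum	PAL	cerebrum
77	Thalamus	THA	cerebrum
78	Thalamus	THA	cerebrum
79	Heschl gyrus	HES	cerebrum
80	Heschl gyrus	HES	cerebrum
81	Superior temporal gyrus	STG	cerebrum
82	Superior temporal gyrus	STG	cerebrum
83	Temporal pole: superior temporal gyrus	TPOsup	cerebrum
84	Temporal pole: superior temporal gyrus	TPOsup	cerebrum
85	Middle temporal gyrus	MTG	cerebrum
86	Middle temporal gyrus	MTG	cerebrum
87	Temporal pole: middle temporal gyrus	TPOmid	cerebrum
88	Temporal pole: middle temporal gyrus	TPOmid	cerebrum
89	Inferior temporal gyrus	ITG	cerebrum
90	Inferior temporal gyrus	ITG	cerebrum
91	Cerebelum_Crus1	CERcr1	cerebellum
92	Cerebelum_Crus1	CERcr1	cerebellum
93	Cerebelum_Crus2	CERcr2	cerebellum
94	Cerebelum_Crus2	CERcr2	cerebellum
95	Cerebelum_3	CER3	cerebellum
96	Cerebelum_3	CER3	cerebellum
97	Cerebelum_4_5	CER4_5	cerebellum
98	Cerebelum_4_5	CER4_5	cerebellum
99	Cerebelum_6	CER6	cerebellum
100	Cerebelum_6	CER6	cerebellum
101	Cerebelum_7	CER7	cerebellum
102	Cerebelum_7	CER7	cerebellum
103	Cerebelum_8	CER8	cerebellum
104	Cerebelum_8	CER8	cerebellum
105	Cerebelum_9	CER9	cerebellum
106	Cerebelum_9	CER9	cerebellum
107	Cerebelum_10	CER10	cerebellum
108	Cerebelum_10	CER10	cerebellum
109	Vermis_1_2	Ver1_2	vermis
110	Vermis_3	Ver_3	vermis
111	Vermis_4_5	Ver4_5	vermis
112	Vermis_6	Ver6	vermis
113	Vermis_7	Ver7	vermis
114	Vermis_8	Ver8	vermis
115	Vermis_9	Ver9	vermis
116	Vermis_10	Ver10	vermis
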