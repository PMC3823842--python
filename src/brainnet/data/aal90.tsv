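index	name	abbreviation	hemisphere	classification
1	Precentral gyrus	PreCG	left	primary
2	Precentral gyrus	PreCG	right	primary
3	Superior frontal gyrus (dorsal)	SFGdor	left	unstated
4	Superior frontal gyrus (dorsal)	SFGdor	right	unstated
5	Orbitofrontal cortex (superior)	ORBsup	left	paralimbic
6	Orbitofrontal cortex (superior)	ORBsup	right	paralimbic
7	Middle frontal gyrus	MFG	left	unstated
8	Middle frontal gyrus	MFG	right	unstated
9	Orbitofrontal cortex (middle)	ORBmid	left	unstated
10	Orbitofrontal cortex (middle)	ORBmid	right	unstated
11	Inferior frontal gyrus (opercular)	IFGoperc	left	association
12	Inferior frontal gyrus (opercular)	IFGoperc	right	association
13	Inferior frontal gyrus (triangular)	IFGtriang	left	association
14	Inferior frontal gyrus (triangular)	IFGtriang	right	association
15	Orbitofrontal cortex (inferior)	ORBinf	left	paralimbic
16	Orbitofrontal cortex (inferior)	ORBinf	right	paralimbic
17	Rolandic operculum	ROL	left	unstated
18	Rolandic operculum	ROL	right	unstated
19	Supplementary motor area	SMA	left	association
20	Supplementary motor area	SMA	right	association
21	Olfactory	OLF	left	unstated
22	Olfactory	OLF	right	unstated
23	Superior frontal gyrus (medial)	SFGmed	left	unstated
24	Superior frontal gyrus (medial)	SFGmed	right	unstated
25	Orbitofrontal cortex (medial)	ORBmed	left	paralimbic
26	Orbitofrontal cortex (medial)	ORBmed	right	paralimbic
27	Rectus gyrus	REC	left	unstated
28	Rectus gyrus	REC	right	unstated
29	Insula	INS	left	unstated
30	Insula	INS	right	unstated
31	Anterior cingulate gyrus	ACG	left	unstated
32	Anterior cingulate gyrus	ACG	right	unstated
33	Middle cingulate gyrus	MCG	left	paralimbic
34	Middle cingulate gyrus	MCG	right	paralimbic
35	Posterior cingulate gyrus	PCG	left	unstated
36	Posterior cingulate gyrus	PCG	right	unstated
37	Hippocampus	HIP	left	unstated
38	Hippocampus	HIP	right	unstated
39	Parahippocampal gyrus	PHG	left	paralimbic
40	Parahippocampal gyrus	PHG	right	paralimbic
41	Amygdala	AMYG	left	unstated
42	Amygdala	AMYG	right	unstated
43	Calcarine cortex	CAL	left	unstated
44	Calcarine cortex	CAL	right	unstated
45	Cuneus	CUN	left	unstated
46	Cuneus	CUN	right	unstated
47	Lingual gyrus	LING	left	unstated
48	Lingual gyrus	LING	right	unstated
49	Superior occipital gyrus	SOG	left	unstated
50	Superior occipital gyrus	SOG	right	unstated
51	Middle occipital gyrus	MOG	left	association
52	Middle occipital gyrus	MOG	right	association
53	Inferior occipital gyrus	IOG	left	unstated
54	Inferior occipital gyrus	IOG	right	unstated
55	Fusiform gyrus	FFG	left	association
56	Fusiform gyrus	FFG	right	association
57	Postcentral gyrus	PoCG	left	unstated
58	Postcentral gyrus	PoCG	right	unstated
59	Superior parietal gyrus	SPG	left	unstated
60	Superior parietal gyrus	SPG	right	unstated
61	Inferior parietal lobule	IPL	left	association
62	Inferior parietal lobule	IPL	right	association
63	Supramarginal gyrus	SMG	left	unstated
64	Supramarginal gyrus	SMG	right	unstated
65	Angular gyrus	ANG	left	unstated
66	Angular gyrus	ANG	right	unstated
67	Precuneus	PCUN	left	association
68	Precuneus	PCUN	right	association
69	Paracentral lobule	PCL	left	unstated
70	Paracentral lobule	PCL	right	unstated
71	Caudate	CAU	left	subcortical
72	Caudate	CAU	right	subcortical
73	Putamen	PUT	left	subcortical
74	Putamen	PUT	right	subcortical
75	Pallidum	PAL	left	subcortical
76	Pallidum	PAL	right	subcortical
77	Thalamus	THA	left	subcortical
78	Thalamus	THA	right	subcortical
79	Heschl gyrus	HES	left	unstated
80	Heschl gyrus	HES	right	unstated
81	Superior temporal gyrus	STG	left	association
82	Superior temporal gyrus	STG	right	association
83	Temporal pole (superior)	TPOsup	left	paralimbic
84	Temporal pole (superior)	TPOsup	right	paralimbic
85	Middle temporal gyrus	MTG	left	association
86	Middle temporal gyrus	MTG	right	association
87	Temporal pole (middle)	TPOmid	left	unstated
88	Temporal pole (middle)	TPOmid	right	unstated
89	Inferior temporal gyrus	ITG	left	association
90	Inferior temporal gyrus	ITG	right	association
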