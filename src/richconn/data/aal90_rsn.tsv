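# AAL-90 cerebral parcellation with resting-state-network assignment.
# The RSN column is a reconstruction assembled from the standard functional
# parcellation literature, constrained to the 10-label vocabulary
# {DMN,SN,VN,SMN,PAC,EXN,ORB,OLF,THA,OTHER}; alt_rsn records a defensible
# alternative assignment where the literature is split ("-" = none).
# Indices are 1-based AAL region numbers (odd = left, even = right).
index	label	hemisphere	rsn	alt_rsn
1	PreCG.L	L	SMN	-
2	PreCG.R	R	SMN	-
3	SFGdor.L	L	EXN	-
4	SFGdor.R	R	EXN	-
5	ORBsup.L	L	ORB	-
6	ORBsup.R	R	ORB	-
7	MFG.L	L	EXN	-
8	MFG.R	R	EXN	-
9	ORBmid.L	L	ORB	-
10	ORBmid.R	R	ORB	-
11	IFGoperc.L	L	EXN	-
12	IFGoperc.R	R	EXN	-
13	IFGtriang.L	L	EXN	-
14	IFGtriang.R	R	EXN	-
15	ORBinf.L	L	ORB	-
16	ORBinf.R	R	ORB	-
17	ROL.L	L	SMN	PAC
18	ROL.R	R	SMN	PAC
19	SMA.L	L	SMN	-
20	SMA.R	R	SMN	-
21	OLF.L	L	OLF	-
22	OLF.R	R	OLF	-
23	SFGmed.L	L	DMN	-
24	SFGmed.R	R	DMN	-
25	ORBsupmed.L	L	ORB	DMN
26	ORBsupmed.R	R	ORB	DMN
27	REC.L	L	ORB	-
28	REC.R	R	ORB	-
29	INS.L	L	SN	-
30	INS.R	R	SN	-
31	ACG.L	L	SN	DMN
32	ACG.R	R	SN	DMN
33	DCG.L	L	SN	OTHER
34	DCG.R	R	SN	OTHER
35	PCG.L	L	DMN	-
36	PCG.R	R	DMN	-
37	HIP.L	L	DMN	OTHER
38	HIP.R	R	DMN	OTHER
39	PHG.L	L	DMN	OTHER
40	PHG.R	R	DMN	OTHER
41	AMYG.L	L	OTHER	SN
42	AMYG.R	R	OTHER	SN
43	CAL.L	L	VN	-
44	CAL.R	R	VN	-
45	CUN.L	L	VN	-
46	CUN.R	R	VN	-
47	LING.L	L	VN	-
48	LING.R	R	VN	-
49	SOG.L	L	VN	-
50	SOG.R	R	VN	-
51	MOG.L	L	VN	-
52	MOG.R	R	VN	-
53	IOG.L	L	VN	-
54	IOG.R	R	VN	-
55	FFG.L	L	VN	OTHER
56	FFG.R	R	VN	OTHER
57	PoCG.L	L	SMN	-
58	PoCG.R	R	SMN	-
59	SPG.L	L	EXN	-
60	SPG.R	R	EXN	-
61	IPL.L	L	EXN	-
62	IPL.R	R	EXN	-
63	SMG.L	L	OTHER	EXN
64	SMG.R	R	OTHER	EXN
65	ANG.L	L	DMN	-
66	ANG.R	R	DMN	-
67	PCUN.L	L	DMN	-
68	PCUN.R	R	DMN	-
69	PCL.L	L	SMN	-
70	PCL.R	R	SMN	-
71	CAU.L	L	SN	-
72	CAU.R	R	SN	-
73	PUT.L	L	SN	-
74	PUT.R	R	SN	-
75	PAL.L	L	SN	OTHER
76	PAL.R	R	SN	OTHER
77	THA.L	L	THA	-
78	THA.R	R	THA	-
79	HES.L	L	PAC	-
80	HES.R	R	PAC	-
81	STG.L	L	PAC	-
82	STG.R	R	PAC	-
83	TPOsup.L	L	OTHER	-
84	TPOsup.R	R	OTHER	-
85	MTG.L	L	DMN	-
86	MTG.R	R	DMN	-
87	TPOmid.L	L	OTHER	-
88	TPOmid.R	R	OTHER	-
89	ITG.L	L	OTHER	-
90	ITG.R	R	OTHER	-
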