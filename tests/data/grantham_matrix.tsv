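aa	S	R	L	P	T	A	V	G	I	F	Y	C	H	Q	N	K	D	E	M	W
S	0	109	144	73	58	99	123	55	142	155	143	112	89	68	46	121	66	80	135	177
R	109	0	102	103	71	111	96	125	98	97	77	180	29	43	85	26	96	54	92	101
L	144	102	0	98	92	96	32	138	5	22	36	198	99	113	153	106	172	139	14	61
P	73	103	98	0	38	27	68	42	96	114	110	169	76	75	90	103	108	94	87	147
T	58	71	92	38	0	58	70	59	89	103	92	149	47	41	65	78	85	66	81	128
A	99	111	96	27	58	0	65	60	94	113	112	195	86	91	111	106	126	107	85	148
V	123	96	32	68	70	65	0	109	30	50	55	191	84	96	133	97	152	121	22	88
G	55	125	138	42	59	60	109	0	136	153	147	158	98	87	79	127	94	98	127	184
I	142	98	5	96	89	94	30	136	0	21	33	198	94	109	149	102	168	134	10	61
F	155	97	22	114	103	113	50	153	21	0	22	205	100	116	158	102	177	140	29	40
Y	143	77	36	110	92	112	55	147	33	22	0	194	83	99	142	85	160	123	35	37
C	112	180	198	169	149	195	191	158	198	205	194	0	174	154	139	202	154	170	196	215
H	89	29	99	76	47	86	84	98	94	100	83	174	0	24	68	32	81	41	86	115
Q	68	43	113	75	41	91	96	87	109	116	99	154	24	0	46	53	61	29	101	130
N	46	85	153	90	65	111	133	79	149	158	142	139	68	46	0	94	23	41	141	174
K	121	26	106	103	78	106	97	127	102	102	85	202	32	53	94	0	102	57	95	110
D	66	96	172	108	85	126	152	94	168	177	160	154	81	61	23	102	0	45	160	191
E	80	54	139	94	66	107	121	98	134	140	123	170	41	29	41	57	45	0	126	152
M	135	92	14	87	81	85	22	127	10	29	35	196	86	101	141	95	160	126	0	67
W	177	101	61	147	128	148	88	184	61	40	37	215	115	130	174	110	191	152	67	0
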