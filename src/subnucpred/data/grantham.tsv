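# Grantham (1974) chemical distance matrix, reconstructed from the defining
# formula D = rho*sqrt(1.833*dc^2 + 0.1018*dp^2 + 0.000399*dv^2) on the
# composition/polarity/volume scales GRAR740101/02/03, scaled to mean 100
# and rounded to integers (matches the published table to within +-1).
res	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0	195	126	107	113	60	86	94	106	96	85	111	27	91	111	99	58	65	148	112
C	195	0	154	170	205	158	174	198	202	198	196	139	169	154	180	112	149	191	215	194
D	126	154	0	45	177	94	81	168	102	172	160	23	108	61	96	66	85	152	191	160
E	107	170	45	0	140	98	41	134	57	139	126	41	94	29	54	80	66	121	152	123
F	113	205	177	140	0	153	100	21	102	22	29	158	114	116	97	155	103	50	40	22
G	60	158	94	98	153	0	98	136	127	138	127	79	42	87	125	55	59	109	184	147
H	86	174	81	41	100	98	0	94	32	99	86	68	76	24	29	89	47	84	115	83
I	94	198	168	134	21	136	94	0	102	5	10	149	96	109	98	142	89	30	61	33
K	106	202	102	57	102	127	32	102	0	106	95	94	103	53	26	121	78	97	110	85
L	96	198	172	139	22	138	99	5	106	0	14	153	98	113	102	144	92	32	61	36
M	85	196	160	126	29	127	86	10	95	14	0	141	87	101	92	135	81	22	67	35
N	111	139	23	41	158	79	68	149	94	153	141	0	90	46	85	46	65	133	174	142
P	27	169	108	94	114	42	76	96	103	98	87	90	0	75	103	73	38	68	147	110
Q	91	154	61	29	116	87	24	109	53	113	101	46	75	0	43	68	41	96	130	99
R	111	180	96	54	97	125	29	98	26	102	92	85	103	43	0	109	71	96	101	77
S	99	112	66	80	155	55	89	142	121	144	135	46	73	68	109	0	58	123	177	143
T	58	149	85	66	103	59	47	89	78	92	81	65	38	41	71	58	0	70	128	92
V	65	191	152	121	50	109	84	30	97	32	22	133	68	96	96	123	70	0	88	55
W	148	215	191	152	40	184	115	61	110	61	67	174	147	130	101	177	128	88	0	37
Y	112	194	160	123	22	147	83	33	85	36	35	142	110	99	77	143	92	55	37	0
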