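# 29 unique AAindex1 amino-acid property scales used by the property-based
# feature extractors. Values exported from the AAindex1 snapshot shipped with
# seqinr 4.2-36 (R data(aaindex), 544 entries, AAindex ver.9 vintage).
accession	description	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
BULH740101	Transfer free energy to surface (Bull-Breese, 1974)	-0.2	-0.45	-0.2	-0.3	-2.33	0.0	-0.12	-2.26	-0.35	-2.46	-1.47	0.08	-0.98	0.16	-0.12	-0.39	-0.52	-1.56	-2.01	-2.24
BULH740102	Apparent partial specific volume (Bull-Breese, 1974)	0.691	0.624	0.558	0.632	0.756	0.592	0.646	0.809	0.767	0.842	0.709	0.596	0.73	0.649	0.728	0.594	0.655	0.777	0.743	0.743
PONP800104	Surrounding hydrophobicity in alpha-helix (Ponnuswamy et al., 1980)	13.65	14.49	10.98	12.55	14.08	15.36	11.59	14.63	11.96	14.01	13.4	12.24	11.51	11.3	11.28	11.26	13.0	12.88	12.06	12.64
PONP800105	Surrounding hydrophobicity in beta-sheet (Ponnuswamy et al., 1980)	14.6	15.9	13.78	13.59	14.18	14.18	15.35	14.1	13.28	16.49	16.23	11.79	14.1	12.02	13.24	13.36	14.5	16.3	13.9	14.76
PONP800106	Surrounding hydrophobicity in turn (Ponnuswamy et al., 1980)	10.67	14.15	10.21	11.71	13.27	10.95	12.07	12.95	9.93	13.07	15.0	10.85	10.62	11.71	11.05	11.18	10.53	13.86	11.41	11.52
MANP780101	Average surrounding hydrophobicity (Manavalan-Ponnuswamy, 1978)	12.97	14.63	10.85	11.89	14.0	12.43	12.16	15.67	11.36	14.9	14.39	11.42	11.37	11.76	11.72	11.23	11.69	15.71	13.93	13.42
EISD840101	Consensus normalized hydrophobicity scale (Eisenberg, 1984)	0.25	0.04	-0.72	-0.62	0.61	0.16	-0.4	0.73	-1.1	0.53	0.26	-0.64	-0.07	-0.69	-1.76	-0.26	-0.18	0.54	0.37	0.02
JOND750101	Hydrophobicity (Jones, 1975)	0.87	1.52	0.66	0.67	2.87	0.1	0.87	3.15	1.64	2.17	1.67	0.09	2.77	0.0	0.85	0.07	0.07	1.87	3.77	2.67
HOPT810101	Hydrophilicity value (Hopp-Woods, 1981)	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
PARJ860101	HPLC parameter (Parker et al., 1986)	2.1	1.4	10.0	7.8	-9.2	5.7	2.1	-8.0	5.7	-9.2	-4.2	7.0	2.1	6.0	4.2	6.5	5.2	-3.7	-10.0	-1.9
JANJ780101	Average accessible surface area (Janin et al., 1978)	27.8	15.5	60.6	68.2	25.5	24.5	50.7	22.8	103.0	27.6	33.5	60.1	51.5	68.7	94.7	42.0	45.0	23.7	34.7	55.2
PONP800107	Accessibility reduction ratio (Ponnuswamy et al., 1980)	3.7	3.03	2.6	3.3	6.6	3.13	3.57	7.69	1.79	5.88	5.21	2.12	2.12	2.7	2.53	2.43	2.6	7.14	6.25	3.03
CHOC760102	Residue accessible surface area in folded protein (Chothia, 1976)	25.0	19.0	50.0	49.0	24.0	23.0	43.0	18.0	97.0	23.0	31.0	63.0	50.0	71.0	90.0	44.0	47.0	18.0	32.0	60.0
ROSG850101	Mean area buried on transfer (Rose et al., 1985)	86.6	132.3	97.8	113.9	194.1	62.9	155.8	158.0	115.5	164.1	172.9	103.3	92.9	119.2	162.2	85.6	106.5	141.0	224.6	177.7
ROSG850102	Mean fractional area loss (Rose et al., 1985)	0.74	0.91	0.62	0.62	0.88	0.72	0.78	0.88	0.52	0.85	0.85	0.63	0.64	0.62	0.64	0.66	0.7	0.86	0.85	0.76
BHAR880101	Average flexibility indices (Bhaskaran-Ponnuswamy, 1988)	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.42
KARP850101	Flexibility parameter for no rigid neighbors (Karplus-Schulz, 1985)	1.041	0.96	1.033	1.094	0.93	1.142	0.982	1.002	1.093	0.967	0.947	1.117	1.055	1.165	1.038	1.169	1.073	0.982	0.925	0.961
KARP850102	Flexibility parameter for one rigid neighbor (Karplus-Schulz, 1985)	0.946	0.878	1.089	1.036	0.912	1.042	0.952	0.892	1.082	0.961	0.862	1.006	1.085	1.025	1.028	1.048	1.051	0.927	0.917	0.93
KARP850103	Flexibility parameter for two rigid neighbors (Karplus-Schulz, 1985)	0.892	0.925	0.932	0.933	0.914	0.923	0.894	0.872	1.057	0.921	0.804	0.93	0.932	0.885	0.901	0.923	0.934	0.913	0.803	0.837
JANJ780102	Percentage of buried residues (Janin et al., 1978)	51.0	74.0	19.0	16.0	58.0	52.0	34.0	66.0	3.0	60.0	52.0	22.0	25.0	16.0	5.0	35.0	30.0	64.0	49.0	24.0
JANJ780103	Percentage of exposed residues (Janin et al., 1978)	15.0	5.0	50.0	55.0	10.0	10.0	34.0	13.0	85.0	16.0	20.0	49.0	45.0	56.0	67.0	32.0	32.0	14.0	17.0	41.0
LEVM780101	Normalized frequency of alpha-helix, with weights (Levitt, 1978)	1.29	1.11	1.04	1.44	1.07	0.56	1.22	0.97	1.23	1.3	1.47	0.9	0.52	1.27	0.96	0.82	0.82	0.91	0.99	0.72
LEVM780102	Normalized frequency of beta-sheet, with weights (Levitt, 1978)	0.9	0.74	0.72	0.75	1.32	0.92	1.08	1.45	0.77	1.02	0.97	0.76	0.64	0.8	0.99	0.95	1.21	1.49	1.14	1.25
LEVM780103	Normalized frequency of reverse turn, with weights (Levitt, 1978)	0.77	0.81	1.41	0.99	0.59	1.64	0.68	0.51	0.96	0.58	0.41	1.28	1.91	0.98	0.88	1.32	1.04	0.47	0.76	1.05
GRAR740102	Polarity (Grantham, 1974)	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
GRAR740103	Volume (Grantham, 1974)	31.0	55.0	54.0	83.0	132.0	3.0	96.0	111.0	119.0	111.0	105.0	56.0	32.5	85.0	124.0	32.0	61.0	84.0	170.0	136.0
MCMT640101	Refractivity (McMeekin et al., 1964), Cited by Jones (1975)	4.34	35.77	12.0	17.26	29.4	0.0	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
PONP800108	Average number of surrounding residues (Ponnuswamy et al., 1980)	6.05	7.86	4.95	5.1	6.62	6.16	5.8	7.51	4.88	7.37	6.39	5.04	5.65	5.45	5.7	5.53	5.81	7.62	6.98	6.73
KYTJ820101	Hydropathy index (Kyte-Doolittle, 1982)	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
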