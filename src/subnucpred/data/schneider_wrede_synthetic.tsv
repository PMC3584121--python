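# SYNTHETIC stand-in for the Schneider-Wrede physicochemical distance matrix.
# The published 1994 matrix is not redistributable here; this stand-in is the
# Euclidean distance over standardized hydropathy (KYTJ820101), hydrophilicity
# (HOPT810101) and side-chain volume (GRAR740103), scaled so max distance = 1
# (the real matrix's [0,1] scale). Symmetric, zero diagonal.
res	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.0	0.1508	0.594	0.6439	0.5931	0.2328	0.5163	0.4982	0.7638	0.4785	0.4056	0.4353	0.2673	0.5045	0.807	0.2208	0.2497	0.3573	0.8425	0.6442
C	0.1508	0.0	0.6612	0.6778	0.4478	0.3744	0.4918	0.3486	0.7632	0.3285	0.2726	0.4813	0.3565	0.5071	0.8054	0.3206	0.2573	0.2106	0.7242	0.5429
D	0.594	0.6612	0.0	0.1545	0.9126	0.5073	0.4729	0.8906	0.3476	0.8546	0.7114	0.3329	0.4018	0.3715	0.3807	0.3993	0.459	0.8121	1.0	0.7848
E	0.6439	0.6778	0.1545	0.0	0.8534	0.6042	0.4223	0.8504	0.1942	0.8126	0.6678	0.3625	0.4697	0.3329	0.2314	0.4686	0.4722	0.7962	0.9127	0.7105
F	0.5931	0.4478	0.9126	0.8534	0.0	0.7878	0.5518	0.1908	0.8339	0.1591	0.214	0.7069	0.6948	0.6313	0.8613	0.686	0.5265	0.3017	0.3643	0.3157
G	0.2328	0.3744	0.5073	0.6042	0.7878	0.0	0.5431	0.7195	0.7621	0.693	0.5917	0.3697	0.1821	0.4977	0.8007	0.1615	0.3134	0.5849	0.9778	0.7625
H	0.5163	0.4918	0.4729	0.4223	0.5518	0.5431	0.0	0.6149	0.4369	0.5637	0.4049	0.2299	0.3646	0.1043	0.453	0.3988	0.2675	0.5827	0.5525	0.3352
I	0.4982	0.3486	0.8906	0.8504	0.1908	0.7195	0.6149	0.0	0.861	0.0536	0.2103	0.7196	0.6625	0.6717	0.8975	0.6358	0.5072	0.1499	0.5532	0.4676
K	0.7638	0.7632	0.3476	0.1942	0.8339	0.7621	0.4369	0.861	0.0	0.8217	0.6812	0.4736	0.6087	0.3801	0.0531	0.6117	0.5646	0.8401	0.8397	0.6668
L	0.4785	0.3285	0.8546	0.8126	0.1591	0.693	0.5637	0.0536	0.8217	0.0	0.1604	0.6746	0.6259	0.6232	0.857	0.6029	0.4663	0.1513	0.5143	0.417
M	0.4056	0.2726	0.7114	0.6678	0.214	0.5917	0.4049	0.2103	0.6812	0.1604	0.0	0.5206	0.4949	0.4629	0.7154	0.4797	0.3256	0.21	0.4777	0.3186
N	0.4353	0.4813	0.3329	0.3625	0.7069	0.3697	0.2299	0.7196	0.4736	0.6746	0.5206	0.0	0.1934	0.1545	0.4978	0.2434	0.2276	0.6411	0.7691	0.5461
P	0.2673	0.3565	0.4018	0.4697	0.6948	0.1821	0.3646	0.6625	0.6087	0.6259	0.4949	0.1934	0.0	0.3162	0.6435	0.0709	0.1734	0.5517	0.8382	0.6158
Q	0.5045	0.5071	0.3715	0.3329	0.6313	0.4977	0.1043	0.6717	0.3801	0.6232	0.4629	0.1545	0.3162	0.0	0.3997	0.3502	0.2597	0.6235	0.654	0.4364
R	0.807	0.8054	0.3807	0.2314	0.8613	0.8007	0.453	0.8975	0.0531	0.857	0.7154	0.4978	0.6435	0.3997	0.0	0.6507	0.6005	0.8806	0.8453	0.6789
S	0.2208	0.3206	0.3993	0.4686	0.686	0.1615	0.3988	0.6358	0.6117	0.6029	0.4797	0.2434	0.0709	0.3502	0.6507	0.0	0.1756	0.5188	0.8566	0.6355
T	0.2497	0.2573	0.459	0.4722	0.5265	0.3134	0.2675	0.5072	0.5646	0.4663	0.3256	0.2276	0.1734	0.2597	0.6005	0.1756	0.0	0.4159	0.6815	0.4612
V	0.3573	0.2106	0.8121	0.7962	0.3017	0.5849	0.5827	0.1499	0.8401	0.1513	0.21	0.6411	0.5517	0.6235	0.8806	0.5188	0.4159	0.0	0.643	0.5131
W	0.8425	0.7242	1.0	0.9127	0.3643	0.9778	0.5525	0.5532	0.8397	0.5143	0.4777	0.7691	0.8382	0.654	0.8453	0.8566	0.6815	0.643	0.0	0.2255
Y	0.6442	0.5429	0.7848	0.7105	0.3157	0.7625	0.3352	0.4676	0.6668	0.417	0.3186	0.5461	0.6158	0.4364	0.6789	0.6355	0.4612	0.5131	0.2255	0.0
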