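	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.3317	0.4161	-0.0440	-0.7150	-0.1138	-0.0668	0.1213	1.0086	-0.3522	-0.1954	-0.0668	0.4054	-0.2313	-0.2986	1.2844	0.4475	0.5267	0.4679	0.5913	-0.2986
C	0.4161	-0.2224	0.4161	-0.4780	-0.3469	-0.0121	0.1759	-0.3231	1.3119	0.5524	-0.0121	0.4600	-0.3590	0.0438	1.3391	0.5021	-0.5172	0.1171	0.6459	-0.0208
D	-0.0440	0.4161	-0.7372	0.3836	0.2916	-0.4722	-0.7260	0.3154	-0.1290	0.4978	1.0318	-0.0001	-0.4136	1.0877	1.2844	0.4475	-0.3896	0.4679	-0.1019	0.2122
E	-0.7150	-0.4780	0.3836	0.4059	0.3138	-0.7377	0.5490	-0.3555	-0.3299	1.2131	-0.5554	-0.2655	0.3017	-0.2764	-0.7728	0.4697	0.1435	-0.4262	-0.3028	0.2345
F	-0.1138	-0.3469	0.2916	0.3138	0.2218	-0.8297	0.4569	0.2456	0.0889	0.4280	-0.4243	-0.0699	-0.6376	-0.0807	0.1160	-0.7209	-0.2362	1.0913	0.5215	0.1425
G	-0.0668	-0.0121	-0.4722	-0.7377	-0.8297	-0.4950	-0.3069	-0.1128	-1.2504	-0.6236	-0.0895	-0.7160	-0.4364	-0.7268	-0.2424	-0.3862	0.0985	-0.6534	-0.5301	-0.5036
H	0.1213	0.1759	-0.7260	0.5490	0.4569	-0.3069	-0.0011	0.4808	0.3240	-0.0301	1.1972	-0.6821	0.8503	0.1544	-0.3420	-0.3035	-0.2242	0.2278	1.4497	-0.4697
I	1.0086	-0.3231	0.3154	-0.3555	0.2456	-0.1128	0.4808	-0.4237	0.5181	0.0463	-0.1128	-0.0461	-0.0542	-0.0569	0.1398	-0.2916	0.4808	0.0164	0.5453	0.5717
K	-0.3522	1.3119	-0.1290	-0.3299	0.0889	-1.2504	0.3240	0.5181	0.7668	0.2950	0.1359	-0.0851	0.1945	0.1918	-0.1223	-0.4484	0.7295	-0.0225	0.3885	0.8204
L	-0.1954	0.5524	0.4978	1.2131	0.4280	-0.6236	-0.0301	0.0463	0.2950	-0.9753	0.4750	0.5417	0.4158	0.5309	-0.1887	0.5838	-0.0301	-0.4944	0.0345	0.3486
M	-0.0668	-0.0121	1.0318	-0.5554	-0.4243	-0.0895	1.1972	-0.1128	0.1359	0.4750	0.3160	0.3827	0.6622	-0.0336	0.1631	0.0193	-0.1891	-0.2480	-0.6842	1.2881
N	0.4054	0.4600	-0.0001	-0.2655	-0.0699	-0.7160	-0.6821	-0.0461	-0.0851	0.5417	0.3827	-0.9370	0.0358	0.4385	-0.0579	-0.2017	0.1652	0.1064	1.3284	-0.4369
P	-0.2313	-0.3590	-0.4136	0.3017	-0.6376	-0.4364	0.8503	-0.0542	0.1945	0.4158	0.6622	0.0358	0.3154	0.0250	-0.1838	0.0779	0.1571	0.7914	0.9148	0.5358
Q	-0.2986	0.0438	1.0877	-0.2764	-0.0807	-0.7268	0.1544	-0.0569	0.1918	0.5309	-0.0336	0.4385	0.0250	-0.2654	-0.0687	0.0752	-0.5387	-0.4152	0.6244	-0.6019
R	1.2844	1.3391	1.2844	-0.7728	0.1160	-0.2424	-0.3420	0.1398	-0.1223	-0.1887	0.1631	-0.0579	-0.1838	-0.0687	0.1280	0.2719	-0.3420	-0.5550	0.1280	0.8476
S	0.4475	0.5021	0.4475	0.4697	-0.7209	-0.3862	-0.3035	-0.2916	-0.4484	0.5838	0.0193	-0.2017	0.0779	0.0752	0.2719	-0.1596	0.6128	0.1485	-0.5754	1.3969
T	0.5267	-0.5172	-0.3896	0.1435	-0.2362	0.0985	-0.2242	0.4808	0.7295	-0.0301	-0.1891	0.1652	0.1571	-0.5387	-0.3420	0.6128	0.6921	0.6332	0.3511	1.4762
V	0.4679	0.1171	0.4679	-0.4262	1.0913	-0.6534	0.2278	0.0164	-0.0225	-0.4944	-0.2480	0.1064	0.7914	-0.4152	-0.5550	0.1485	0.6332	0.5744	-0.4009	0.0310
W	0.5913	0.6459	-0.1019	-0.3028	0.5215	-0.5301	1.4497	0.5453	0.3885	0.0345	-0.6842	1.3284	0.9148	0.6244	0.1280	-0.5754	0.3511	-0.4009	0.1280	-0.2510
Y	-0.2986	-0.0208	0.2122	0.2345	0.1425	-0.5036	-0.4697	0.5717	0.8204	0.3486	1.2881	-0.4369	0.5358	-0.6019	0.8476	1.3969	1.4762	0.0310	-0.2510	-0.2246
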