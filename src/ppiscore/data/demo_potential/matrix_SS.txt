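	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.7255	0.4277	0.3731	1.0884	0.3033	0.6380	0.1329	-0.3661	0.1703	-0.4069	-0.3428	0.4170	0.6966	-0.6924	-0.0902	-0.4571	-0.1547	0.4796	-0.0902	-0.4692
C	0.4277	-0.6162	-0.4886	-0.2432	-0.5584	0.6927	-0.1001	0.3818	-0.0627	-0.1291	0.4050	-0.2214	0.3458	0.4609	-0.0355	-0.1793	-0.5056	0.5342	1.3507	-0.7023
D	0.3731	-0.4886	-0.3201	0.3953	-0.1022	0.6380	-0.1547	-0.9257	-0.5228	0.5094	-0.3428	1.1102	0.0035	0.0008	-0.0902	0.4592	0.1329	-0.4367	0.6029	-0.2869
E	1.0884	-0.2432	0.3953	0.4175	-0.3676	0.6603	-0.1325	-0.3438	-0.3183	-0.1615	-0.5437	0.4393	0.7188	0.4285	-0.0680	1.1745	0.5606	0.0963	0.6252	0.2461
F	0.3033	-0.5584	-0.1022	-0.3676	-0.4597	0.5682	0.4686	-0.1482	1.1991	-0.2535	0.2806	0.3472	-0.2895	0.3364	0.5331	-0.5269	-0.6300	-0.2834	0.5331	0.1541
G	0.6380	0.6927	0.6380	0.6603	0.5682	-0.4833	0.8034	0.5920	0.8407	0.7744	0.6153	0.6820	0.9616	0.6712	0.8679	0.7241	0.8034	0.7445	0.8679	0.8943
H	0.1329	-0.1001	-0.1547	-0.1325	0.4686	0.8034	-0.6826	1.1856	0.0480	-0.2416	-0.5829	1.2755	0.1688	0.1661	0.0751	-0.0687	0.0106	0.2394	0.0751	0.1016
I	-0.3661	0.3818	-0.9257	-0.3438	-0.1482	0.5920	1.1856	-0.8175	0.1243	-0.6352	-0.3888	-0.0344	-0.7357	0.3602	0.1515	0.0077	1.1856	0.0281	0.1515	-0.1098
K	0.1703	-0.0627	-0.5228	-0.3183	1.1991	0.8407	0.0480	0.1243	-0.3201	-0.3865	-0.6997	0.6198	0.8993	0.6089	-0.2930	0.6619	0.3356	-0.2340	-0.2930	0.1389
L	-0.4069	-0.1291	0.5094	-0.1615	-0.2535	0.7744	-0.2416	-0.6352	-0.3865	-0.0474	0.0812	0.5534	0.1398	0.5426	1.4324	-0.0977	-0.2416	0.2104	-0.5135	0.3602
M	-0.3428	0.4050	-0.3428	-0.5437	0.2806	0.6153	-0.5829	-0.3888	-0.6997	0.0812	0.3276	0.3943	0.2684	-0.0220	0.5802	-0.4799	-0.5829	0.0514	0.1747	0.2012
N	0.4170	-0.2214	1.1102	0.4393	0.3472	0.6820	1.2755	-0.0344	0.6198	0.5534	0.3943	-0.6376	-0.3580	-0.9361	1.3401	-0.4132	-0.1108	1.2167	-0.0462	-0.4253
P	0.6966	0.3458	0.0035	0.7188	-0.2895	0.9616	0.1688	-0.7357	0.8993	0.1398	0.2684	-0.3580	-0.9257	0.0366	0.0102	0.7827	0.4565	0.8031	-0.3263	0.2598
Q	-0.6924	0.4609	0.0008	0.4285	0.3364	0.6712	0.1661	0.3602	0.6089	0.5426	-0.0220	-0.9361	0.0366	0.4394	-0.4625	0.4923	0.1661	1.2059	-0.0571	-0.2538
R	-0.0902	-0.0355	-0.0902	-0.0680	0.5331	0.8679	0.0751	0.1515	-0.2930	1.4324	0.5802	1.3401	0.0102	-0.4625	0.1397	-0.0041	0.0751	-0.2069	-0.2658	0.1661
S	-0.4571	-0.1793	0.4592	1.1745	-0.5269	0.7241	-0.0687	0.0077	0.6619	-0.0977	-0.4799	-0.4132	0.7827	0.4923	-0.0041	0.5452	0.6245	-0.1275	-0.5637	0.3100
T	-0.1547	-0.5056	0.1329	0.5606	-0.6300	0.8034	0.0106	1.1856	0.3356	-0.2416	-0.5829	-0.1108	0.4565	0.1661	0.0751	0.6245	-0.6826	-0.0483	-0.1480	0.3892
V	0.4796	0.5342	-0.4367	0.0963	-0.2834	0.7445	0.2394	0.0281	-0.2340	0.2104	0.0514	1.2167	0.8031	1.2059	-0.2069	-0.1275	-0.0483	-0.8002	-0.3892	0.0427
W	-0.0902	1.3507	0.6029	0.6252	0.5331	0.8679	0.0751	0.1515	-0.2930	-0.5135	0.1747	-0.0462	-0.3263	-0.0571	-0.2658	-0.5637	-0.1480	-0.3892	0.1397	0.1661
Y	-0.4692	-0.7023	-0.2869	0.2461	0.1541	0.8943	0.1016	-0.1098	0.1389	0.3602	0.2012	-0.4253	0.2598	-0.2538	0.1661	0.3100	0.3892	0.0427	0.1661	-0.2129
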