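	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.3201	0.4277	-0.0324	-0.7033	-0.1022	-0.4606	0.1329	1.0202	-0.3405	-0.1837	-0.0551	0.4170	-0.2197	-0.2869	1.2961	0.4592	0.5384	0.4796	0.6029	-0.2869
C	0.4277	-0.2108	0.4277	-0.4663	-0.3352	-0.4059	0.1876	-0.3114	1.3236	0.5641	-0.0005	0.4717	-0.3473	0.0554	1.3507	0.5138	-0.5056	0.1288	0.6576	-0.0091
D	-0.0324	0.4277	-0.7255	0.3953	0.3033	-0.4606	-0.7144	0.3271	-0.1174	0.5094	1.0435	0.0116	-0.4020	1.0994	1.2961	0.4592	-0.3779	0.4796	-0.0902	0.2239
E	-0.7033	-0.4663	0.3953	0.4175	0.3255	-0.7260	0.5606	-0.3438	-0.3183	1.2248	-0.5437	-0.2539	0.3134	-0.2647	-0.7611	0.4814	0.1552	-0.4145	-0.2911	0.2461
F	-0.1022	-0.3352	0.3033	0.3255	0.2335	-0.8181	0.4686	0.2573	0.1005	0.4396	-0.4126	-0.0582	-0.6259	-0.0690	0.1277	-0.7093	-0.2245	1.1029	0.5331	0.1541
G	-0.4606	-0.4059	-0.4606	-0.7260	-0.8181	-1.5819	-0.2953	-0.1011	-1.2387	-0.6119	-0.0778	-0.7043	-0.4247	-0.7151	-0.2307	-1.0677	-0.2953	-0.6418	-0.5184	-0.4920
H	0.1329	0.1876	-0.7144	0.5606	0.4686	-0.2953	0.0106	0.4924	0.3356	-0.0184	1.2088	-0.6704	0.8619	0.1661	-0.3303	-0.2918	-0.2126	0.2394	1.4614	-0.4581
I	1.0202	-0.3114	0.3271	-0.3438	0.2573	-0.1011	0.4924	-0.4120	0.5298	0.0580	-0.1011	-0.0344	-0.0425	-0.0452	0.1515	-0.2800	0.4924	0.0281	0.5570	0.5834
K	-0.3405	1.3236	-0.1174	-0.3183	0.1005	-1.2387	0.3356	0.5298	0.7785	0.3067	0.1476	-0.0734	0.2062	0.2035	-0.1106	-0.4367	0.7411	-0.0109	0.4002	0.8321
L	-0.1837	0.5641	0.5094	1.2248	0.4396	-0.6119	-0.0184	0.0580	0.3067	-0.9637	0.4867	0.5534	0.4275	0.5426	-0.1770	0.5955	-0.0184	-0.4827	0.0461	0.3602
M	-0.0551	-0.0005	1.0435	-0.5437	-0.4126	-0.0778	1.2088	-0.1011	0.1476	0.4867	0.3276	0.3943	0.6739	-0.0220	0.1747	0.0310	-0.1775	-0.2363	-0.6726	1.2998
N	0.4170	0.4717	0.0116	-0.2539	-0.0582	-0.7043	-0.6704	-0.0344	-0.0734	0.5534	0.3943	-0.9253	0.0474	0.4502	-0.0462	-0.1900	0.1769	0.1181	1.3401	-0.4253
P	-0.2197	-0.3473	-0.4020	0.3134	-0.6259	-0.4247	0.8619	-0.0425	0.2062	0.4275	0.6739	0.0474	0.3270	0.0366	-0.1721	0.0896	0.1688	0.8031	0.9265	0.5475
Q	-0.2869	0.0554	1.0994	-0.2647	-0.0690	-0.7151	0.1661	-0.0452	0.2035	0.5426	-0.0220	0.4502	0.0366	-0.2538	-0.0571	0.0868	-0.5271	-0.4036	0.6361	-0.5902
R	1.2961	1.3507	1.2961	-0.7611	0.1277	-0.2307	-0.3303	0.1515	-0.1106	-0.1770	0.1747	-0.0462	-0.1721	-0.0571	0.1397	0.2835	-0.3303	-0.5433	0.1397	0.8592
S	0.4592	0.5138	0.4592	0.4814	-0.7093	-1.0677	-0.2918	-0.2800	-0.4367	0.5955	0.0310	-0.1900	0.0896	0.0868	0.2835	-0.1479	0.6245	0.1602	-0.5637	1.4086
T	0.5384	-0.5056	-0.3779	0.1552	-0.2245	-0.2953	-0.2126	0.4924	0.7411	-0.0184	-0.1775	0.1769	0.1688	-0.5271	-0.3303	0.6245	0.7037	0.6449	0.3628	1.4878
V	0.4796	0.1288	0.4796	-0.4145	1.1029	-0.6418	0.2394	0.0281	-0.0109	-0.4827	-0.2363	0.1181	0.8031	-0.4036	-0.5433	0.1602	0.6449	0.5860	-0.3892	0.0427
W	0.6029	0.6576	-0.0902	-0.2911	0.5331	-0.5184	1.4614	0.5570	0.4002	0.0461	-0.6726	1.3401	0.9265	0.6361	0.1397	-0.5637	0.3628	-0.3892	0.1397	-0.2394
Y	-0.2869	-0.0091	0.2239	0.2461	0.1541	-0.4920	-0.4581	0.5834	0.8321	0.3602	1.2998	-0.4253	0.5475	-0.5902	0.8592	1.4086	1.4878	0.0427	-0.2394	-0.2129
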