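patient	slope_low	slope_mid	slope_high	abs_r_low	abs_r_mid	abs_r_high
1	0.000116	0.000228	0.006246	0.20	0.14	0.09
2	0.000302	0.000453	0.006941	0.13	0.17	0.05
3	0.000271	-0.000766	0.007815	0.11	0.16	0.09
4	0.000205	-0.000639	0.008389	0.28	0.10	0.07
5	0.000254	0.000787	0.002268	0.24	0.11	0.07
6	0.000123	-0.000751	0.002566	0.22	0.14	0.08
7	0.000122	0.000574	0.004457	0.28	0.15	0.07
8	0.000118	0.000697	0.001109	0.16	0.14	0.07
9	0.000310	0.000111	0.004003	0.11	0.10	0.05
10	0.000175	0.000848	0.004635	0.20	0.14	0.10
11	0.000162	-0.000560	0.006605	0.27	0.08	0.10
12	0.000162	0.000315	0.008695	0.17	0.17	0.08
13	0.000306	0.000652	0.007029	0.19	0.16	0.08
14	0.000137	0.000112	0.009008	0.13	0.16	0.07
15	-0.000315	-0.000449	0.002743	0.13	0.18	0.07
16	0.000160	0.000843	0.009275	0.19	0.13	0.07
17	0.000313	0.000734	0.006408	0.28	0.12	0.05
18	0.000172	-0.000412	0.001995	0.21	0.17	0.05
19	0.000284	0.000120	0.002553	0.25	0.19	0.08
20	0.000168	0.000855	0.005470	0.31	0.19	0.07
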