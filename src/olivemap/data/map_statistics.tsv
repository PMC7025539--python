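parent	chrom	n_markers	length_cM	n_bins
female	1	268	232.874	98
female	2	355	216.454	101
female	3	308	207.305	91
female	4	222	221.467	72
female	5	262	179.227	81
female	6	378	333.996	120
female	7	304	229.924	113
female	8	291	207.785	99
female	9	225	198.075	75
female	10	527	474.952	187
female	11	402	443.421	160
female	12	382	263.992	119
female	13	298	252.841	97
female	14	262	260.901	88
female	15	369	241.160	113
female	16	264	205.234	89
female	17	294	233.648	95
female	18	357	188.878	97
female	19	340	290.418	112
female	20	182	154.145	63
female	21	205	186.505	71
female	22	286	231.551	90
female	23	225	225.217	80
male	1	522	165.979	95
male	2	341	169.818	82
male	3	312	127.713	63
male	4	377	117.929	65
male	5	387	89.749	52
male	6	773	192.604	100
male	7	487	143.868	85
male	8	263	133.481	53
male	9	317	166.185	72
male	10	715	283.975	148
male	11	607	196.433	113
male	12	484	210.657	101
male	13	443	286.844	82
male	14	379	112.722	62
male	15	632	140.747	96
male	16	199	127.797	54
male	17	369	129.562	65
male	18	424	169.573	85
male	19	404	196.065	91
male	20	337	127.779	65
male	21	289	95.021	50
male	22	364	151.210	77
male	23	312	102.030	73
female	total	7006	5679.970	2311
male	total	9737	3537.741	1829
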