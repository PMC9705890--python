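organism	strain	subspecies	size_mb	gc_percent	cds	assembly_level	accession
L. delbrueckii subsp. bulgaricus	ATCC BAA-365	bulgaricus	1.85695	49.7	1579	Complete	CP000412.1
L. delbrueckii subsp. bulgaricus	ATCC 11842	bulgaricus	1.865	49.7	1561	Complete	CR954253.1
L. delbrueckii subsp. bulgaricus	2038	bulgaricus	1.87292	49.7	1562	Complete	CP000156.1
L. delbrueckii subsp. bulgaricus	CNCM I-1519	bulgaricus	1.79654	49.9	1630	Contig	AGHW01
L. delbrueckii subsp. bulgaricus	INRA-MIG	bulgaricus	1.85324	49.8	1692	Scaffold	CCET01
L. delbrueckii subsp. bulgaricus	DSM 20081	bulgaricus	1.75853	49.9	1533	Scaffold	JQAV01
L. delbrueckii subsp. bulgaricus	MN-BM-F01	bulgaricus	1.87507	49.7	1585	Complete	CP013610.1
L. delbrueckii subsp. bulgaricus	CFL1	bulgaricus	1.75792	49.8	1539	Contig	CZPS01
L. delbrueckii subsp. bulgaricus	LBB.B5	bulgaricus	1.77788	49.8	1558	Contig	LUGK01
L. delbrueckii subsp. bulgaricus	DSM 20080	bulgaricus	1.86818	49.8	1564	Complete	CP019120.1
L. delbrueckii subsp. bulgaricus	ND04	bulgaricus	1.86175	49.6	1538	Complete	CP016393.1
L. delbrueckii subsp. bulgaricus	MBT 92059	bulgaricus	1.83117	49.8	1648	Scaffold	QOVB01
L. delbrueckii subsp. bulgaricus	L99	bulgaricus	1.84811	49.7	1575	Complete	CP017235.1
L. delbrueckii subsp. bulgaricus	KLDS1.0207	bulgaricus	1.86918	49.8	1620	Complete	CP032451.1
L. delbrueckii subsp. bulgaricus	FAM 21277	bulgaricus	2.01984	49.2	1830	Contig	VBSR01
L. delbrueckii subsp. bulgaricus	NBRC 13953	bulgaricus	1.72582	50.0	1519	Contig	BJMY01
L. delbrueckii subsp. bulgaricus	KLDS1.1011	bulgaricus	1.88749	49.8	1634	Complete	CP041280.1
L. delbrueckii subsp. bulgaricus	LJJ	bulgaricus	1.89109	49.5	1604	Complete	CP049052.1
L. delbrueckii subsp. bulgaricus	ACA-DC 87	bulgaricus	1.856	49.8	1579	Complete	LT899687.1
L. delbrueckii subsp. delbrueckii	KACC 13439	delbrueckii	1.76619	50.0	1485	Contig	LHPL01
L. delbrueckii subsp. delbrueckii	KCTC 13731	delbrueckii	1.91051	50.0	1600	Complete	CP018216.1
L. delbrueckii subsp. delbrueckii	DSM 20074	delbrueckii	1.95372	49.6	1577	Complete	CP018615.1
L. delbrueckii subsp. delbrueckii	TUA4408L	delbrueckii	2.01244	49.9	1718	Complete	CP021136.1
L. delbrueckii subsp. delbrueckii	NBRC 3534	delbrueckii	1.78742	50.3	1588	Contig	BJLM01
L. delbrueckii subsp. delbrueckii	NBRC 3202	delbrueckii	1.91031	50.1	1653	Complete	AP019750.1
L. delbrueckii subsp. indicus	JCM 15610	indicus	1.87741	49.5	1627	Contig	LGAS01
L. delbrueckii subsp. indicus	DSM 15996	indicus	1.86357	49.6	1621	Scaffold	AZFL01
L. delbrueckii subsp. indicus	JCM 15610	indicus	2.02186	49.4	1694	Complete	CP018614.1
L. delbrueckii subsp. jakobsenii	ZN7a-9	jakobsenii	1.73081	50.2	1552	Contig	ALPY01
L. delbrueckii subsp. jakobsenii	DSM 26046	jakobsenii	1.74924	50.3	1568	Scaffold	JQCG01
L. delbrueckii subsp. jakobsenii	DSM 26046	jakobsenii	1.8918	50.1	1614	Complete	CP018218.1
L. delbrueckii subsp. jakobsenii	DSM 26046	jakobsenii	1.78119	50.1	1585	Scaffold	PUFG01
L. delbrueckii subsp. lactis	CRL581	lactis	2.13682	49.6	1639	Scaffold	ATBQ01
L. delbrueckii subsp. lactis	KCCM 34717	lactis	2.26338	49.1	1905	Complete	CP018215.1
L. delbrueckii subsp. lactis	DSM 20072	lactis	2.16598	49.0	1793	Complete	CP022988.1
L. delbrueckii subsp. lactis	KCTC 3034	lactis	2.23761	49.0	1889	Complete	CP023139.1
L. delbrueckii subsp. lactis	NBRC 3734	lactis	1.81291	50.2	1653	Contig	BJLO01
L. delbrueckii subsp. lactis	lactis1	lactis	2.05032	49.6	1694	Complete	LS991409.1
L. delbrueckii subsp. lactis	NWC_2_2	lactis	2.269179	48.7	1934	Complete	CP031023.1
L. delbrueckii subsp. sunkii	JCM 17838	sunkii	1.94526	50.1	1713	Contig	LGHR01
L. delbrueckii subsp. sunkii	JCM 17838	sunkii	2.00434	50.1	1726	Complete	CP018217.1
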