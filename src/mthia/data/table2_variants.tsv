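category	gene_notation	genomic_notation	gene_pos	ecoli_base	ecoli_pos	crw_letter	ci_univ	ci_1ry	ci_2ry	ci_tot
unlikely	249A>G	m.896A>G	249	G	524	g	3	4	5	19
undetermined	67A>U	m.714A>T	67	G	112	g	3	3	5	17
undetermined	90C>U	m.737C>T	90				NI	NI	NI	NI
undetermined	103G>C	m.750G>C	103				NI	NI	NI	NI
undetermined	125A>G	m.772A>G	125	C	271	x	0	2	2	6
undetermined	167A>G	m.814A>G	167	G	351	o	2	4	4	16
undetermined	282A>U	m.929A>T	282	G	557	x	0	0	3	3
undetermined	296G>A	m.943G>A	296	G	577	g	3	3	5	17
undetermined	308A>G	m.955A>G	308				NI	NI	NI	NI
undetermined	313C>A	m.960C>A	313				NI	NI	NI	NI
undetermined	314U>A	m.961T>A	314				NI	NI	NI	NI
undetermined	314InsC(5)	m.961InsC(5)	314				NI	NI	NI	NI
undetermined	314delU	m.961delT	314				NI	NI	NI	NI
undetermined	361A>U	m.1008A>T	361	G	711	w	1	2	4	10
undetermined	364C>A	m.1011C>A	364	G	714	g	3	2	4	14
undetermined	474A>G	m.1121A>G	474				NI	NI	NI	NI
undetermined	485U>C	m.1132T>C	485	C	879	w	1	4	4.5	14.5
undetermined	878C>G	m.1525C>G	878				NI	NI	NI	NI
undetermined	888U>C	m.1535T>C	888				NI	NI	NI	NI
NEE	40G>A	m.687G>A	40	G	46	w	1	3	5	13
NEE	257C>U	m.904C>T	257	A	532	o	2	4	5	17
NEE	265U>A	m.912T>A	265	G	540	w	1	1	4	8
NEE	277A>U	m.924A>T	277	U	552	w	1	1	4	8
NEE	620U>A	m.1267T>A	620	U	1062	u	3	3	4.5	16.5
NEE	642G>C	m.1289G>C	642	U	1083	o	2	2	5	13
NEE	698G>A	m.1345G>A	698	G	1215	o	2	3	5	15
NEE	701G>A	m.1348G>A	701	G	1218	w	1	2	5	11
NEE	727A>G	m.1374A>G	727	C	1245	w	1	1	2.5	6.5
NEE	733G>A	m.1380G>A	733	G	1294	w	1	1	4.5	8.5
NEE	742G>A	m.1389G>A	742	G	1304	g	3	2	5	15
NEE	897A>U	m.1544A>T	897	C	1479	x	0	3	4	10
NEE	929G>A	m.1576G>A	929	G	1511	o	2	4	5	17
NEE	939G>A	m.1586G>A	939	C	1521	w	1	4	5	15
likely	450G>A	m.1097G>A	450	G	809	o	2	4	5	17
likely	507A>C	m.1154A>C	507	A	901	a	3	3	5	17
likely	676G>A	m.1323G>A	676	G	1193	o	2	4	4.5	16.5
likely	680G>A	m.1327G>A	680	A	1197	w	1	3	5	13
likely	852U>C	m.1499T>C	852	G	1415	w	1	1	4.5	8.5
expectedly	232U>C	m.879T>C	232	C	507	c	3	3	5	17
expectedly	255G>A	m.902G>A	255	G	530	G	4	5	5	23
expectedly	522G>A	m.1169G>A	522	U	916	o	2	5	5	19
expectedly	533U>G	m.1180T>G	533	G	927	w	1	4	5	15
expectedly	579C>G	m.1226C>G	579	C	972	C	4	5	5	23
expectedly	580G>A	m.1227G>A	580	G	973	g	3	4	5	19
expectedly	910A>C	m.1557A>C	910	A	1492	A	4	4	4	20
expectedly	915G>A	m.1562G>A	915	G	1497	G	4	6	5	25
expectedly	919C>U	m.1566C>T	919	C	1501	c	3	5	5	21
proven	847C>U	m.1494C>T	847	A	1410	w	1	4	4	14
proven	908A>G	m.1555A>G	908	U	1490	w	1	3	4	12
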