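id	pattern	genes	bp	mp
1	DDD	51	1	2
2	DDS	77	5	2
3	DDI	11	6	4
4	DSD	286	22	11
5	DSS	537	31	4
6	DSI	145	43	3
7	DID	60	12	7
8	DIS	64	5	2
9	DII	88	18	1
10	SDD	146	17	3
11	SDS	224	13	0
12	SDI	37	12	4
13	SSD	1290	92	26
14	SSS	28392	328	31
15	SSI	882	100	16
16	SID	299	17	3
17	SIS	254	15	3
18	SII	142	17	2
19	IDD	136	11	4
20	IDS	107	11	2
21	IDI	38	17	1
22	ISD	232	18	7
23	ISS	307	16	3
24	ISI	133	27	4
25	IID	46	6	3
26	IIS	38	6	1
27	III	44	9	3
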