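# Published reference screen: 52 intergenomic SNP assays against a 10x amphidiploid (B. napus) BAC library of 82,944 clones.
# Per-assay counts of putative clones, total and per assay nucleotide.
assay_id	n_total	nt1_base	nt1_count	nt2_base	nt2_count
386-17c	95	C	87	G	8
386-17a	60	T	51	C	9
386-14d	2	A	0	G	2
386-14c	129	A	126	G	3
386-13	110	A	108	G	2
386-8	406	C	400	T	6
637-3	215	T	209	G	6
637-5	243	C	233	A	10
637-8a	402	T	336	C	66
637-8b	214	C	172	T	42
637-11	538	G	427	A	111
11428	194	A	142	T	52
11426	236	A	145	G	91
11424	3124	T	3124	A	0
11411	102	T	79	G	23
11410	80	A	67	T	13
11406	66	A	58	G	8
11405	68	G	54	T	14
11396	22	C	22	G	0
11395	16	G	11	A	5
11392a	7	T	7	C	0
11392b	20	A	10	C	10
11385-b	21	G	10	A	11
11385-c	27	G	11	T	16
11382a	67	T	31	C	36
11382b	68	G	36	C	32
11376	406	A	44	T	362
11372	607	A	607	C	0
11356	60	A	2	G	58
11355	182	A	98	G	84
11354	432	T	82	G	350
479-18	143	G	65	C	79
479-13d	60	G	51	A	9
479-13b	60	A	52	G	8
479-12b	125	G	121	T	4
479-12a	123	T	118	C	5
479-9	152	A	152	G	0
479-3	286	A	278	G	8
BolI-5	301	T	297	C	4
BolI-3	298	C	298	T	0
11308	377	T	201	C	177
11307	209	C	118	T	91
11303	0	G	0	A	0
11301	1	T	0	C	1
217-1	117	A	19	G	98
217-5	741	A	741	G	0
217-6a	31	C	17	A	14
217-6b	498	G	488	T	10
217-7	127	C	74	G	53
217-9	96	A	64	G	32
578-5	95	A	63	G	32
578-6	128	A	105	C	23
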