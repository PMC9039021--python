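patient_id	isolate_id	collection_route	csf_volume_ml	conc_37	conc_150	conc_300	tissue_h3_status
1	1	VAD	3	16793	15170	8583	negative
2	1	VAD	2.4	2972	1486	546	negative
3	1	VAD	2.8	676	417	306	negative
4	1	VAD	4	361	122	101	negative
5	1	VAD	2.5	53	35	20	negative
6	1	IO	2	0	0	0	negative
7	1	IO	4	973	683	669	negative
8	1	IO	4	64	47	142	negative
9	1	LP	3	16	10	0	positive
10	1	LP	2	1	3	4	positive
11	1	IO	13.3	66	108	87	positive
11	2	IO	13.3	320	165	137	positive
11	3	LP	1	4	7	3	positive
12	1	IO	10	27	14	6	positive
12	2	IO	10	19	8	9	positive
13	1	VAD	5	106	81	51	unavailable
14	1	VAD	4.8	387	108	67	negative
15	1	LP	3.5	0	0	0	negative
16	1	IO	1.2	0	0	0	negative
17	1	VAD	2	9	6	0	unavailable
18	1	LP	2	2	0	0	unavailable
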