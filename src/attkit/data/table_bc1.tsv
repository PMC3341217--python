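family	plants_tested	target_positive	excision_positive	excision_no_recombinase	recombinase_no_target
Bxb1.9.7	48	36	20	0	1
Bxb1.9.8	18	14	14	5	0
Bxb1.9.11	6	6	6	0	0
Bxb1.9.17	40	32	32	15	1
Bxb1.9.23	51	41	36	0	9
Bxb1.9.26	49	46	22	0	0
Bxb1.9.29	18	16	12	0	1
Bxb1.9.31	44	10	9	0	24
Bxb1.9.44	32	28	26	17	0
Bxb1.12.52	27	14	8	0	6
Bxb1.12.61	9	6	6	1	2
Bxb1.12.69	8	2	2	0	3
Bxb1.12.72	9	4	1	0	3
Bxb1.12.73	9	3	3	1	6
Bxb1.12.74	9	9	4	0	0
Bxb1.12.79	9	8	6	1	0
Bxb1.12.81	9	7	3	0	0
Bxb1.12.82	9	8	7	0	1
Bxb1.12.83	9	9	3	1	0
Bxb1.28.1	27	26	22	6	0
Bxb1.28.2	18	18	14	0	0
Bxb1.28.3	16	16	11	1	0
Bxb1.28.4	9	8	8	3	0
Bxb1.28.6	26	24	24	11	0
Bxb1.28.7	17	15	13	0	0
Bxb1.28.8	3	3	3	2	0
Bxb1.28.9	18	17	17	4	0
Bxb1.28.10	23	22	16	3	0
Bxb1.28.11	8	7	7	2	0
Bxb1.35.1	18	9	5	0	0
Bxb1.35.2	36	28	17	7	0
Bxb1.35.3	103	47	27	1	9
Bxb1.35.15	23	19	14	5	0
Bxb1.35.29	24	23	23	8	0
Bxb1.35.32	23	23	23	0	0
Bxb1.35.33	23	19	16	1	0
Bxb1.35.36	24	23	23	5	0
Bxb1.35.41	15	14	9	0	0
Bxb1.35.44	17	17	16	0	0
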