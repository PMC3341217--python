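family	plants_tested	target_positive	recombinase_positive	excision_and_recombinase	excision_no_unexcised
Bxb1.9.17	31	30	29	28	28
Bxb1.9.31	31	31	19	19	19
Bxb1.12.69	16	16	14	14	14
Bxb1.12.72	16	15	7	7	3
Bxb1.35.15	28	26	25	24	24
Bxb1.35.33	46	45	36	35	13
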