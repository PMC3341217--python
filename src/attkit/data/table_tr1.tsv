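family	plants_tested	recombinase_and_target	excision_positive	excision_no_unexcised
Bxb1.9	48	28	28	17
Bxb1.12	78	31	28	26
Bxb1.28	18	18	18	16
Bxb1.35	44	28	26	13
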