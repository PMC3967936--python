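region	Grk	Dpp	Mid	n_cells
R1	3	1	0	9
R2	2	1	0	12
R3	1	1	0	12
R4	0	1	0	60
R5	3	0	0	30
R6	2	0	0	40
R7	1	0	0	40
R8	0	0	0	317
R9	3	0	1	14
R10	2	0	1	29
R11	1	0	1	41
R12	0	0	1	356
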