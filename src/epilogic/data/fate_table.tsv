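dpERK	Mirr	Pnt	Rho	Aos	Br	fate
0	0	0	0	0	0	F1
1	1	0	0	0	1	F2
1	0	0	0	0	0	F3
0	0	0	0	0	1	F4
2	1	1	0	1	1	F5
1	1	0	1	0	0	F6
2	0	1	0	0	0	F7
2	1	1	2	1	0	F8
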