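id	founder_pairs	hap_1.1	hap_2.2	hap_4.1	hap_9.2
1	C/D	0	0	1	0
2	D/F	0	0	1	0
3	D	0	1	0	0
4	D	0	0	0	0
5	C/E	0	0	0	0
6	A/B/C/D	1	1	1	0
7	A/B	0	1	0	1
8	A/B/C	0	0	0	1
9	A/B/C	0	0	0	0
10	B	0	0	0	0
11	B	0	0	0	0
12	B	1	0	0	0
13	B	0	0	0	1
15	C	0	0	0	0
17	E	0	0	0	0
19	A/B/C	1	1	0	0
20	F	0	0	0	0
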