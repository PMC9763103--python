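hap_id	chrom	start_bp	end_bp	length_printed_mb	carriers	carrier_fp_sets	main_fp	n_main_fp_carriers	carrier_diagnoses	length_discrepant	carriers_ambiguous	fp_conflict
1.1	1	44527042	48054945	3.53	12,6,19	B|A/B/C/D|A/B/C	B	3	TS,OCD_probable,ADHD_probable|TS|TS	0	0	.
2.1	2	13000487	15987485	2.99	12,6,9	B|A/B/C/D|A/B/C	B	3	TS,OCD_probable,ADHD_probable|TS|TS,ADHD_probable	0	0	9:B
2.2	2	211041963	214017954	2.98	7,3,6,19	A/B|D|A/B/C/D|A/B/C	A/B	3	TS,ADHD|TS|TS|TS	0	0	19:A/B
4.1	4	154028117	164629683	10.62	2,1,6	D/F|C/D|A/B/C/D	D	3	TS|TS|TS	1	0	.
4.2	4	164642592	168832405	4.19	2,3,1	D/F|D|C/D	D	3	TS|TS|TS	0	0	.
5.1	5	107466596	110400753	2.93	10,7,12	B|A/B|B	B	3	TS,ADHD_probable|TS,ADHD|TS,OCD_probable,ADHD_probable	0	0	.
6.1	6	11239710	15065694	3.83	1,15,19	C/D|C|A/B/C	C	3	TS|TS,ADHD|TS	0	0	.
9.1	9	101864325	106732943	4.87	7,11,15,6	A/B|A/B|C|A/B/C/D	A/B	3	TS,ADHD|TS,ADHD|TS,ADHD|TS	0	1	.
9.2	9	130138362	132407549	2.27	7,13,8	A/B|B|A/B/C	B	3	TS,ADHD|TS,ADHD|TS,ADHD	0	0	.
18.1	18	66447780	69214658	2.77	7,12,19	A/B|B|A/B/C	B	3	TS,ADHD|TS,OCD_probable,ADHD_probable|TS	0	0	.
20.1	20	9153822	12651396	3.55	5,1,6	C/E|C/D|A/B/C/D	C	3	CMVT,ADHD_probable|TS|TS	1	0	.
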