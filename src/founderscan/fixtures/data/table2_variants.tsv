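hap_id	chrom	pos_bp	id	ref	alt	af_amr	minor_allele	max_af	max_af_pop	consequence_verbatim	consequence	impact	gene	aa_substitution	sift	sift_score	polyphen	polyphen_score	cadd_phred	pli	missense_z	ncer_percentile
1.1	1	45617469	rs780636281	C	A	0.001392	A	0.00139153	AMR	Missense variant	missense	Moderate	NASP	P/T	deleterious	0.04	possibly_damaging	0.621	25.81	1	0.61	.
9.2	9	131619052	rs570357965	G	A	0.001976	A	0.00197628	AMR	Missense variant	missense	Moderate	RAPGEF1	S/L	deleterious_low_confidence	0	probably_damaging	0.999	23.8	1	3.13	.
2.2	2	211617876	rs1219527473	T	G	0.000661	G	0.000660599	AMR	Intron variant, downstream gene variant	intronic	Modifier	ERBB4	.	.	.	.	.	17.69	.	.	99.47
2.2	2	213098737	rs562279749	T	C	0.000661	C	0.00152643	FIN	Intron variant	intronic	Modifier	IKZF2	.	.	.	.	.	21.2	.	.	97.26
4.1	4	157889911	rs564274930	C	A	0.000513	A	0.00051267	AMR	Intron variant, non-coding transcript variant	noncoding_transcript	Modifier	AC017037.5	.	.	.	.	.	16.67	.	.	95.03
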