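chrom	pos	ref	alt	is_indel	indel_len	qual	call_rate	near_indel_bp	consequence	gene_id	sift	provean	aa_pos	aa_len	ortho11	rnacov	ac_WA	an_WA	nhom_WA	ac_W1	an_W1	nhom_W1
1	10000	C	T	False	0	60.0	0.95	500	stop_gained	GENE_LETHAL_A	0.0	-6.1	120	400	True	800	4	140	0	0	140	0
1	20000	G	A	False	0	55.0	0.96	500	splice_donor	GENE_LETHAL_B		-4.0			True	600	3	140	0	2	140	0
1	30000	A	G	False	0	70.0	0.97	500	missense	GENE_LETHAL_C	0.2	-1.0	50	300	True	900	5	140	0	0	140	0
1	40000	T	C	False	0	65.0	0.94	500	missense	GENE_LETHAL_D	0.01	-5.5	80	250	True	700	8	140	1	0	140	0
1	50000	CA	C	True	-1	58.0	0.95		frameshift	GENE_PLAIN_E		-6.0	30	200	True	500	2	140	0	0	140	0
1	60000	G	C	False	0	62.0	0.96	500	synonymous	GENE_LETHAL_A			200	400	True	800	6	140	0	3	140	0
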