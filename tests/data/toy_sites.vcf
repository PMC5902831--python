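##fileformat=VCFv4.2
##INFO=<ID=CR,Number=1,Type=Float,Description="Genotype call rate">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">
##contig=<ID=1,length=20000>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
1	1000	.	AT	A	50.0	PASS	CR=0.9;CSQ_CLASS=other
1	1002	.	G	A	50.0	PASS	CR=0.9;CSQ_CLASS=synonymous
1	998	.	C	T	50.0	PASS	CR=0.9;CSQ_CLASS=synonymous
1	2000	.	A	G	15.0	PASS	CR=0.9;CSQ_CLASS=missense
1	3000	.	C	T	50.0	PASS	CR=0.6;CSQ_CLASS=missense
1	5000	.	A	G	50.0	PASS	CR=0.9;CSQ_CLASS=synonymous
1	6000	.	C	T	50.0	PASS	CR=0.95;CSQ_CLASS=missense
1	7000	.	G	A	50.0	PASS	CR=0.9;CSQ_CLASS=stop_gained
1	8000	.	T	C	50.0	PASS	CR=0.88;CSQ_CLASS=synonymous
1	9000	.	A	C	50.0	PASS	CR=0.92;CSQ_CLASS=missense
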