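order_index	rsid	chrom	pos	build	exon	codon_change	aa_change	ref	alt
1	rs740623580	23	2749185	GRCg7b	Exon 1	CGA>CAA	R9Q	G	A
2	rs869007872	23	2749241	GRCg7b	Exon 1	TCT>TTT	S27F	C	T
3	rs794503708	23	2749275	GRCg7b	Exon 1	CCC>CTC	P39L	C	T
4	rs733753324	23	2749792	GRCg7b	Exon 2	TTG>TTC	L43F	G	C
5	rs731472668	23	2749926	GRCg7b	Exon 2	CAT>CGT	H88R	A	G
6	rs738943348	23	2749941	GRCg7b	Exon 2	CTG>CCG	L93P	T	C
7	rs739602946	23	2749952	GRCg7b	Exon 2	TCA>CCA	S97P	T	C
8	rs738898886	23	2750212	GRCg7b	Exon 3	ATA>ATG	I101M	A	G
9	rs313465722	23	2750348	GRCg7b	Exon 3	TAT>CAT	Y147H	T	C
10	rs735870559	23	2751919	GRCg7b	Exon 5	GTG>TTG	V215L	G	T
11	rs316593393	23	2752402	GRCg7b	Exon 6	AAG>GAG	K272E	A	G
12	rs733511284	23	2752431	GRCg7b	Exon 6	GGT>GGG	G281G	T	G
13	rs314800215	23	2752791	GRCg7b	Exon 7	GAG>AAG	E325K	G	A
14	rs738163839	23	2752814	GRCg7b	Exon 7	GAC>GAA	D332E	C	A
15	rs737604974	23	2753525	GRCg7b	Exon 8	GAG>AAG	E343K	G	A
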