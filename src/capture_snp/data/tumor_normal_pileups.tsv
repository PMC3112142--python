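# Published strand-split pileup rows (forward;reverse counts) for the seven
# positions where one patient's leukocyte and tumor genotypes differ, with the
# published genotype calls. Two printed coverages disagree with their count
# sums by one read (B4GALNT1 Tu 123 vs 122; CTDSP2 Tu 3580 vs 3579); calls are
# made from the counts.
patient	gene	pos	chrom	ref	sample	coverage	A	C	G	T	genotype	rsid
A	B4GALNT1	56310248	12	C	Leu	154	30;70	0;54	0;0	0;0	AC	rs715930
A	B4GALNT1	56310248	12	C	Tu	123	61;48	7;6	0;0	0;0	AA	rs715930
A	LOC643266	47216571	22	G	Leu	96	27;0	0;0	69;0	0;0	GA	rs12172263
A	LOC643266	47216571	22	G	Tu	115	115;0	0;0	0;0	0;0	AA	rs12172263
A	LOC644033	4412	8	G	Leu	127	0;0	0;0	21;24	42;40	TG	na
A	LOC644033	4412	8	G	Tu	74	0;0	0;0	7;4	31;32	TT	na
A	PARP1	224639987	1	A	Leu	102	23;24	0;0	0;55	0;0	GA	rs1805414
A	PARP1	224639987	1	A	Tu	61	4;4	0;0	11;42	0;0	GG	rs1805414
B	CTDSP2	56503706	12	C	Leu	118	0;0	51;16	0;0	11;40	CT	na
B	CTDSP2	56503706	12	C	Tu	3580	3;0	64;82	4;1	1235;2190	TT	na
B	PAXIP1	154391302	7	A	Leu	114	13;16	0;0	26;59	0;0	GA	rs935037
B	PAXIP1	154391302	7	A	Tu	286	0;0	0;0	64;222	0;0	GG	rs935037
B	MDM1	67006894	12	G	Leu	52	27;10	0;0	8;7	0;0	AG	rs962976
B	MDM1	67006894	12	G	Tu	99	74;8	0;0	13;4	0;0	AA	rs962976
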