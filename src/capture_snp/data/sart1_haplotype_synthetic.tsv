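# SART1 four-site breast-cancer-risk haplotype definition. The first two
# sites are scored on their minor alleles (code 1), the last two on their
# major alleles (code 0). Only the rs660118 allele pair (minor C / major G)
# is published; the allele letters of the other three sites are SYNTHETIC
# placeholders sufficient for encoding tests.
rsid	minor	major
rs660118	C	G
rs679581	T	C
rs754532	A	G
rs735942	G	A
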