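locus	forward_primer	reverse_primer	amplicon_min	amplicon_max
16S	GAGGTTGATCATGGCTCAG	ACAACGCAGGTCCATCT	238	248
ITS	AGGTAGCCGTATCGGAAGGT	YACAGCGTTTTCGGTTTATTT	231	250
rnpB	GTGCAATTTTTGGATAATCG	TGGGTTGCTAGCTTGAGG	248	254
rpoB	CTGAAGAACGTCTCTTGCAC	CGAGAGACAACCCCTTTRTT	245	245
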