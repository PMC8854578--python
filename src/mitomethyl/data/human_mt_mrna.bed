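# 13 human mtDNA protein-coding genes (GRCh38 chrM / NC_012920.1)
# BED: chrom, 0-based start, end, gene, category, strand
chrM	3306	4262	ND1	mRNA	+
chrM	4469	5511	ND2	mRNA	+
chrM	5903	7445	CO1	mRNA	+
chrM	7585	8269	CO2	mRNA	+
chrM	8365	8572	ATP8	mRNA	+
chrM	8526	9207	ATP6	mRNA	+
chrM	9206	9990	CO3	mRNA	+
chrM	10058	10404	ND3	mRNA	+
chrM	10469	10766	ND4L	mRNA	+
chrM	10759	12137	ND4	mRNA	+
chrM	12336	14148	ND5	mRNA	+
chrM	14148	14673	ND6	mRNA	-
chrM	14746	15887	CYB	mRNA	+
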