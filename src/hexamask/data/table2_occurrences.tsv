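# Reference occurrence counts of low-energy W/S masks (EDR peptide) in
# curated human promoters of Alzheimer's-disease-related genes, as
# published.  External, database-version-dependent data: shipped for
# reference only, never recomputed.
# The mean for SWSWWS (entry 5) was printed without a minus sign;
# transcribed here as -37.89, consistent with the per-mask summary.
entry	mean_score	mask	gene	count
1	-38.66	WSSWSS	GPX1	1
2	-38.20	SWSSWS	APOE	2
3	-38.02	SSSWSS	PPARA	3
3	-38.02	SSSWSS	GAP43	4
4	-37.96	WSSWSW	SOD2	1
4	-37.96	WSSWSW	APOE	1
5	-37.89	SWSWWS	SOD2	1
5	-37.89	SWSWWS	PPARA	2
5	-37.89	SWSWWS	GAP43	1
6	-37.73	SWSSSS	PPARA	2
6	-37.73	SWSSSS	GAP43	1
6	-37.73	SWSSSS	APOE	2
7	-37.65	WWSWSS	SOD2	1
8	-37.45	WSSWWS	PPARG	1
9	-37.36	WWSSWS	SOD2	1
9	-37.36	WWSSWS	GPX1	1
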