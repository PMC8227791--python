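# peptide: EDR
mask	n	mean	std	best_score	best_sequence
SWSWSS	NA	-38.67	3.24	-44.71	GAGTGG
WSSWSS	NA	-38.66	2.35	-44.01	ACGTCG
SWSSWS	NA	-38.20	3.50	-42.76	CACGTG
SSSWSS	NA	-38.02	2.27	-43.31	GGGACG
WSSWSW	NA	-37.96	2.25	-43.78	AGGAGT
SWSWWS	NA	-37.89	2.66	-44.43	GAGTAC
SWSSSS	NA	-37.73	2.61	-42.76	GTCCCC
WWSWSS	NA	-37.65	2.87	-43.04	TACTCG
WSSWWS	NA	-37.45	2.38	-42.99	TGGTTG
WWSSWS	NA	-37.36	2.88	-44.04	AAGCTC
WSSSSS	NA	-37.34	2.64	-43.10	AGGCCC
SSSSSS	NA	-37.31	3.02	-42.81	CGGGCG
SSSSWS	NA	-37.21	2.37	-41.61	GGGGTG
WSWSWW	NA	-37.17	2.87	-42.70	AGAGTA
SSSWWS	NA	-37.14	2.57	-41.29	GGGTAG
SSWSSS	NA	-37.08	2.39	-41.00	GCACGC
WWSWSW	NA	-37.06	3.34	-44.27	AAGAGT
WWSWWS	NA	-37.04	2.23	-42.15	AAGTTG
WWSSSS	NA	-37.04	2.23	-42.27	AAGGGG
WSWSSS	NA	-37.03	2.66	-43.21	AGACCG
WSSWWW	NA	-36.96	2.29	-41.35	AGGAAA
SSWSWS	NA	-36.85	2.68	-42.59	GGACTG
WSSSSW	NA	-36.81	2.38	-40.87	ACGCGT
WSWSSW	NA	-36.71	2.10	-41.49	TGAGGA
WSSSWS	NA	-36.62	2.19	-40.55	AGCGTC
WSWWSW	NA	-36.59	2.56	-41.18	AGAAGT
WWSWWW	NA	-36.47	1.91	-39.94	ATGTTA
SWWSWS	NA	-36.44	3.33	-41.99	GAAGTC
WSWSWS	NA	-36.34	3.19	-41.94	ACAGTG
WWSSSW	NA	-36.05	2.83	-41.93	TAGCCA
WWWSWS	NA	-35.86	3.38	-41.59	TAACTC
SSWWSS	NA	-35.79	2.06	-41.18	GCAACG
WWSSWW	NA	-35.74	2.17	-39.62	AACGTA
WSWWSS	NA	-35.59	2.58	-41.05	AGTTCG
WSWWWW	NA	-35.16	3.00	-40.00	AGTTTA
WWWSSW	NA	-35.14	2.55	-42.01	AAACCT
SWWSSS	NA	-35.13	2.52	-39.57	GAACCC
WWWSWW	NA	-35.06	2.63	-39.44	AATGTT
WWWSSS	NA	-34.93	2.14	-39.43	AAACGG
WSSSWW	NA	-34.77	2.58	-39.61	AGCCTA
SSWWWS	NA	-34.45	2.59	-39.13	GCTTAG
WWWWSW	NA	-34.32	2.84	-40.54	AAAAGT
WSWWWS	NA	-34.25	2.64	-40.14	AGATAG
SWWWSS	NA	-33.78	2.37	-38.47	GAAACC
WWWWSS	NA	-33.26	2.26	-38.85	TAAACC
SWWWWS	NA	-31.90	2.05	-36.60	CAAAAG
WWWWWS	NA	-31.82	2.63	-39.52	TTAAAG
WWWWWW	NA	-31.76	2.17	-38.93	AAAAAA
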