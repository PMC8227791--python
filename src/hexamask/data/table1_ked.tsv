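# peptide: KED
mask	n	mean	std	best_score	best_sequence
SWSWSS	NA	-16.15	3.57	-26.56	CAGAGG
WSWSWS	NA	-15.96	2.94	-24.02	ACAGTG
WSWSSW	NA	-15.91	2.86	-20.52	TCTGGA
WWSWSW	NA	-15.72	2.68	-22.32	AACACT
SSWSWS	NA	-15.55	3.91	-22.54	GCAGTG
WSWSWW	NA	-15.53	3.12	-22.33	ACAGAA
SSSWSS	NA	-15.36	2.93	-20.72	CGCTGG
SSWSSS	NA	-15.34	3.09	-22.25	CGTGGG
WSWSSS	NA	-15.31	3.73	-21.34	AGTCCC
WWWSWS	NA	-15.28	3.36	-23.85	TTTCAG
SWWSWS	NA	-15.27	3.07	-21.63	GTTGTG
WWSWSS	NA	-15.26	3.52	-24.69	TACAGG
SWWWSS	NA	-15.25	2.84	-23.29	CAAACG
WSSWSS	NA	-15.23	3.53	-25.71	AGCTCG
WSSWSW	NA	-15.10	4.66	-25.11	AGCAGT
WWWSSS	NA	-15.01	3.75	-25.22	ATACGG
SWSSWS	NA	-15.01	4.27	-22.33	CACCAG
WSSSWS	NA	-15.00	3.64	-25.23	AGGGTC
SSWWWS	NA	-14.89	3.88	-22.08	GCTTAG
WSWWSS	NA	-14.87	2.70	-22.29	TGTTCC
SSWWSS	NA	-14.86	2.84	-20.45	CGAAGG
WSWWWW	NA	-14.74	3.13	-18.83	AGTATA
WWSSSS	NA	-14.63	3.94	-21.87	ATCGGC
SWWSSS	NA	-14.62	3.14	-21.51	CATCCG
WWSSSW	NA	-14.62	3.20	-22.91	AAGGGT
WSWWWS	NA	-14.56	2.98	-22.72	TCATTG
SSSWWS	NA	-14.51	2.66	-19.82	GGGTAG
SWWWWS	NA	-14.48	3.29	-22.39	GATATG
SWSWWS	NA	-14.38	2.97	-18.72	GACAAG
WWSSWS	NA	-14.36	3.83	-26.00	TACGAC
WWWWSS	NA	-14.35	3.07	-22.83	TTAACG
SWSSSS	NA	-14.28	4.52	-26.11	GAGGGG
WSSWWS	NA	-14.02	3.10	-20.15	ACCTAC
WSSSWW	NA	-14.01	2.56	-17.09	ACGGTA
SSSSWS	NA	-13.98	4.40	-22.68	GGGCTG
WSWWSW	NA	-13.97	2.36	-19.40	TGTTGA
WWSWWS	NA	-13.93	3.51	-23.04	AAGAAG
WSSSSW	NA	-13.91	4.71	-23.66	ACGGGT
WWWWWS	NA	-13.86	3.07	-21.03	TATAAG
WSSSSS	NA	-13.71	4.14	-26.54	AGGGGC
WWWWSW	NA	-13.61	3.46	-20.26	TATTGA
WWWSSW	NA	-13.47	3.69	-21.40	TTTCCA
WWSWWW	NA	-13.38	3.44	-19.74	ATGTTA
WSSWWW	NA	-13.27	4.01	-17.57	AGCATA
WWSSWW	NA	-13.06	3.12	-21.35	ATGGTA
SSSSSS	NA	-12.78	3.86	-20.21	GCGCCG
WWWWWW	NA	-12.50	3.93	-21.35	TATATA
WWWSWW	NA	-11.90	3.24	-22.18	ATAGTA
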