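# Synthetic RNU2 allele spectrum: per-allele counts are invented;
# only the summary statistics constrained by published data are real:
# 53 distinct alleles in a combined sample of 504 haploid genotypes.
# Both SMM theta estimators depend on the spectrum only through n_A and n.
allele_size	count
5	6
6	6
7	7
8	8
11	10
12	10
13	11
14	12
16	13
18	14
19	15
20	16
21	16
23	17
24	18
25	18
27	19
28	19
29	19
31	20
32	19
36	18
37	17
38	17
39	16
40	16
41	15
43	14
44	13
45	12
51	8
52	8
53	7
54	6
56	5
57	5
58	4
59	4
61	3
63	3
64	3
65	2
66	2
67	2
68	2
69	2
71	1
73	1
74	1
77	1
79	1
81	1
82	1
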