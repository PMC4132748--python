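mutation_id	g_mrca	g_lower	g_upper	family_id	alleles	meioses
c.4987-578_5074+342del1008				F1816	28	17
c.213-11T>G	87	67	111	F2749	22	6
c.213-11T>G	87	67	111	F3103	22	6
c.4186-1787_4357+4122dup	73	52	100	F3173	29	5
c.4186-1787_4357+4122dup	73	52	100	F3653	14	2
c.68_69delAG	61	47	77	F2541	37	0
c.68_69delAG	61	47	77	F3079	37	0
c.68_69delAG	61	47	77	F3261	37	0
c.68_69delAG	61	47	77	F2979	47	5
c.5266dupC	72	49	107	F1704	21	20
c.5266dupC	72	49	107	F1973	19	4
c.5266dupC	72	49	107	F3715b	19	0
c.5266dupC	72	49	107	F3574	13;35	0
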