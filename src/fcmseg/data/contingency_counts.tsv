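table	row	a	b	c	d
baseline	singleton_vs_twin	36	2	58	4
neurological	hie	8	30	15	47
prognosis	perinatal_death	1	37	0	62
prognosis	rds	3	35	4	58
complications	any_complication	1	37	13	49
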