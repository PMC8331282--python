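table	row	group	mean	sd	n
baseline	maternal_age_years	A	26.85	5.88	38
baseline	maternal_age_years	B	26.71	7.62	62
baseline	parity	A	1.15	1.02	38
baseline	parity	B	1.09	1.01	62
baseline	gestational_weeks	A	31.25	2.15	38
baseline	gestational_weeks	B	31.16	2.37	62
neurological	nbna_score	A	34.45	4.25	38
neurological	nbna_score	B	33.65	4.72	62
neurological	nse_at_birth	A	26.28	7.21	38
neurological	nse_at_birth	B	27.11	7.42	62
neurological	nse_day3	A	33.22	9.58	38
neurological	nse_day3	B	32.16	10.05	62
prognosis	birth_weight_g	A	2721.42	241.15	38
prognosis	birth_weight_g	B	2511.72	203.36	62
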