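table	row	printed	annotation
baseline	maternal_age_years	0.103	published value matches the Welch statistic (0.103); pooled gives 0.097
baseline	parity	0.287	
baseline	gestational_weeks	0.191	
neurological	nbna_score	0.854	
neurological	nse_at_birth	0.549	
neurological	nse_day3	0.521	
prognosis	birth_weight_g	4.661	
prognosis	perinatal_death	1.648	
prognosis	rds	0.075	
complications	any_complication	6.579	
baseline	singleton_vs_twin	0.059	
neurological	hie	0.131	
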