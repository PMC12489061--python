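# paralogrisk v0.1.0
# mode=both speed=4000.0 min_exposure=300 margin=300
# speed_bp_per_hr=4000.0 min_exposure_bp=300 co_margin_bp=300 naive_extend=False both_ends=False
# repeat_coverage_bp=6000 repeat_coverage_bp_unmerged=6000 genome_bp=100000
t_hours	L_bp	at_risk_bp	genome_fraction
0	0	0	0
0.5	2000	23544	0.23544
1	4000	35652	0.35652
1.5	6000	47652	0.47652
2	8000	57701	0.57701
2.5	10000	65701	0.65701
3	12000	73701	0.73701
3.5	14000	81701	0.81701
4	16000	89191	0.89191
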