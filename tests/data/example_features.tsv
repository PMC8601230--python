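egg_id	group	mode	responder	time_to_first_s	first_duration_s	n_osc_60	n_osc_120	freq_per_10min	auc_60	cessation_s	censored
NC_000	NC	strontium	True	217.5	37.5	5	5	0.8333333333333334	65.55387252086967	1027.5	False
NC_001	NC	strontium	True	285.0	52.5	4	4	0.6666666666666666	65.69974484291646	1095.0	False
SOV_000	SOV	strontium	True	292.5	52.5	5	5	0.8333333333333334	67.8662021409431	870.0	False
SOV_001	SOV	strontium	True	240.0	30.0	3	3	0.5	46.595908606855346	892.5	False
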