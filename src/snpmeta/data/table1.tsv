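study_id	snp_id	population	subgroup	cohort_id	n_case	n_control	case_AA	case_AG	case_GG	control_AA	control_AG	control_GG	or_point	or_ci_low	or_ci_high
Gretarsdottir	rs2200733	European	non-Asian	Gretarsdottir	29474	6222	514	6754	22206	71	1189	4962
Shi	rs2200733	Chinese	Asian	Shi	811	688	200	405	206	180	344	164
Bevan	rs2200733	European	non-Asian	Bevan	5859	6281	NR	NR	NR	NR	NR	NR
Cao	rs2200733	Chinese	Asian	Cao	1388	1629	311	692	385	342	809	478
Su	rs2200733	Chinese	Asian	Su	816	816	194	417	205	191	408	217
Su	rs6843082	Chinese	Asian	Su	816	816	49	305	462	60	316	440
B23	rs6843082	Chinese	Asian	B23	167	176	12	66	89	20	78	78
B7	rs6843082	Brazilian	non-Asian	B7	240	285	128	95	17	140	120	25
Zhao	rs6843082	Chinese	Asian	Zhao	476	501	34	187	255	40	203	258
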