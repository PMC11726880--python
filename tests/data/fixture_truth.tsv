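gene_id	is_de	direction	effect_size	affected_samples
g00000	False	none	0.0	
g00001	False	none	0.0	
g00002	False	none	0.0	
g00003	False	none	0.0	
g00004	False	none	0.0	
g00005	False	none	0.0	
g00006	False	none	0.0	
g00007	True	up	1.5	case_000,case_001,case_002,case_003,case_004,case_005
g00008	True	up	1.5	case_000,case_001,case_002,case_003,case_004,case_005
g00009	False	none	0.0	
g00010	True	down	1.5	case_000,case_001,case_002,case_003,case_004,case_005
g00011	False	none	0.0	
g00012	False	none	0.0	
g00013	False	none	0.0	
g00014	True	up	1.5	case_000,case_001,case_002,case_003,case_004,case_005
g00015	False	none	0.0	
g00016	True	down	1.5	case_000,case_001,case_002,case_003,case_004,case_005
g00017	False	none	0.0	
g00018	False	none	0.0	
g00019	True	down	1.5	case_000,case_001,case_002,case_003,case_004,case_005
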