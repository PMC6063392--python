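fine_id	level_a	level_b	level_c
10	CerebralCortex_L	Frontal_L	none
11	CerebralCortex_R	Frontal_R	none
20	WhiteMatter_L	AnteriorWM_L	none
21	WhiteMatter_R	AnteriorWM_R	none
30	none	none	Lateral Ventrical_body_L
31	none	none	Lateral Ventrical_body_R
32	none	none	III_and_IV_ventricle
40	CerebralCortex_L	Limbic_L	Hippocampus_L
41	CerebralCortex_R	Limbic_R	Hippocampus_R
50	none	none	none
60	none	none	none
70	none	none	none
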