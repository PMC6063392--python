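level	name
A	CerebralCortex_L
A	CerebralCortex_R
A	WhiteMatter_L
A	WhiteMatter_R
B	Frontal_L
B	Frontal_R
B	Parietal_L
B	Parietal_R
B	Temporal_L
B	Temporal_R
B	Limbic_L
B	Limbic_R
B	Occipital_L
B	Occipital_R
B	midbrain_L
B	midbrain_R
B	Cerebellum_R
B	Cerebellum_L
B	Pons_L
B	Pons_R
B	AnteriorWM_L
B	AnteriorWM_R
B	PosteriorWM_L
B	PosteriorWM_R
B	CorpusCallosum_L
B	CorpusCallosum_R
B	InferiorWM_L
B	InferiorWM_R
B	LimbicWM_L
B	LimbicWM_R
C	Amygdala_L
C	Amygdala_R
C	Hippocampus_L
C	Hippocampus_R
C	Caudate_L
C	Caudate_R
C	Putamen_L
C	Putamen_R
C	Globus pallidus_L
C	Globus pallidus_R
C	Thalamus_L
C	Thalamus_R
C	Genu of Corpus Callosum_L
C	Genu of Corpus Callosum_R
C	Body of Corpus Callosum_L
C	Body of Corpus Callosum_R
C	Splenium_of Corpus Callosum_L
C	Splenium_of Corpus Callosum_R
C	Anterial insular cortex_L
C	Anterial insular cortex_R
C	Posterial insular cortex_L
C	Posterial insular cortex_R
C	Lateral Ventrical_Frontal_L
C	Lateral Ventrical_body_L
C	Lateral Ventrical_atrium_L
C	Lateral Ventrical_Occipital_L
C	Lateral Ventrical_Inferior_L
C	Lateral Ventrical_Frontal_R
C	Lateral Ventrical_body_R
C	Lateral Ventrical_atrium_R
C	Lateral Ventrical_Occipital_R
C	Lateral Ventrical_Inferior_R
C	III_and_IV_ventricle
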