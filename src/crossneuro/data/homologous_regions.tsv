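label	hemisphere	human_components	mouse_components	compartment	has_expression
Agranular insula	L	AVI;AAIC;MI	Agranular insular area	cortical	1
Agranular insula	R	AVI;AAIC;MI	Agranular insular area	cortical	1
Amygdala	L	Amygdala	Cortical subplate	non_cortical	1
Amygdala	R	Amygdala	Cortical subplate	non_cortical	1
Anterior cingulate area	L	A24pr;a24;p24pr;p24;24dd;24dv;p32pr;d32;a32pr;p32;s32	Anterior cingulate area	cortical	1
Anterior cingulate area	R	A24pr;a24;p24pr;p24;24dd;24dv;p32pr;d32;a32pr;p32;s32	Anterior cingulate area	cortical	1
Bed nucleus of stria terminalis	L	Bed nucleus of stria terminalis	Bed nucleus of stria terminalis	non_cortical	1
Bed nucleus of stria terminalis	R	Bed nucleus of stria terminalis	Bed nucleus of stria terminalis	non_cortical	1
Caudoputamen	L	Caudate;Putamen	Caudoputamen	non_cortical	1
Caudoputamen	R	Caudate;Putamen	Caudoputamen	non_cortical	1
Cerebellar cortex	L	Cerebellar cortex	Cerebellar cortex	non_cortical	1
Cerebellar cortex	R	Cerebellar cortex	Cerebellar cortex	non_cortical	1
Dentate gyrus, molecular layer	L	Dentate gyrus, molecular layer	Dentate gyrus, molecular layer	non_cortical	1
Dentate gyrus, molecular layer	R	Dentate gyrus, molecular layer	Dentate gyrus, molecular layer	non_cortical	1
CA1	L	CA1	CA1	non_cortical	1
CA1	R	CA1	CA1	non_cortical	1
CA3	L	CA3	CA3	non_cortical	1
CA3	R	CA3	CA3	non_cortical	1
Entorhinal cortex	L	EC	Entorhinal area	cortical	1
Entorhinal cortex	R	EC	Entorhinal area	cortical	1
Globus pallidus	L	Globus Pallidus	Pallidum	non_cortical	1
Globus pallidus	R	Globus Pallidus	Pallidum	non_cortical	1
Hippocampus	L	Hippocampus	Hippocampal region	non_cortical	1
Hippocampus	R	Hippocampus	Hippocampal region	non_cortical	1
Hypothalamus	L	Hypothalamus	Hypothalamus	non_cortical	1
Hypothalamus	R	Hypothalamus	Hypothalamus	non_cortical	1
Medial amygdalar nucleus	L	Medial amygdalar nucleus	Medial amygdalar nucleus	non_cortical	0
Medial amygdalar nucleus	R	Medial amygdalar nucleus	Medial amygdalar nucleus	non_cortical	0
Medial preoptic area	L	Medial preoptic area	Medial preoptic area	non_cortical	0
Medial preoptic area	R	Medial preoptic area	Medial preoptic area	non_cortical	0
Nucleus accumbens	L	Nucleus accumbens	Striatum ventral region	non_cortical	1
Nucleus accumbens	R	Nucleus accumbens	Striatum ventral region	non_cortical	1
Perirhinal area	L	PeEc;TF;PHA2;PHA3	Perirhinal area	cortical	1
Perirhinal area	R	PeEc;TF;PHA2;PHA3	Perirhinal area	cortical	1
Piriform cortex	L	Pir	Piriform cortex	cortical	1
Piriform cortex	R	Pir	Piriform cortex	cortical	1
Posterior parietal association areas	L	5m;5mv;5L	Posterior parietal association areas	cortical	1
Posterior parietal association areas	R	5m;5mv;5L	Posterior parietal association areas	cortical	1
Primary auditory area	L	A1	Primary auditory area	cortical	1
Primary auditory area	R	A1	Primary auditory area	cortical	1
Primary motor area	L	4	Primary motor area	cortical	1
Primary motor area	R	4	Primary motor area	cortical	1
Primary somatosensory area	L	1;2;3a;3b	Primary somatosensory area	cortical	1
Primary somatosensory area	R	1;2;3a;3b	Primary somatosensory area	cortical	1
Primary visual area	L	V1	Primary visual area	cortical	1
Primary visual area	R	V1	Primary visual area	cortical	1
Retrosplenial area	L	RSC	Retrosplenial area	cortical	1
Retrosplenial area	R	RSC	Retrosplenial area	cortical	1
Subiculum	L	PreS	Subiculum	non_cortical	1
Subiculum	R	PreS	Subiculum	non_cortical	1
Temporal association areas	L	FFC;PIT;TE1a;TE1p;TE2a;TF;STV;STSvp;STSva	Temporal association areas	cortical	1
Temporal association areas	R	FFC;PIT;TE1a;TE1p;TE2a;TF;STV;STSvp;STSva	Temporal association areas	cortical	1
Thalamus	L	Thalamus	Thalamus	non_cortical	1
Thalamus	R	Thalamus	Thalamus	non_cortical	1
Ventral orbital area	L	10r;10v	Ventral orbital area	cortical	1
Ventral orbital area	R	10r;10v	Ventral orbital area	cortical	1
Brain stem	M	Brainstem	Midbrain;Hindbrain	non_cortical	1
Medulla	M	Medulla	Medulla	non_cortical	1
Midbrain	M	Midbrain	Midbrain	non_cortical	1
Pons	M	Pons	Pons	non_cortical	1
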