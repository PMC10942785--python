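label	hemisphere	beta_human	sig_human	beta_mouse	sig_mouse
Agranular insula	L	0.200	1	-0.558	1
Agranular insula	R	0.164	1	-0.522	1
Amygdala	L	0.305	1	0.163	1
Amygdala	R	0.201	1	0.151	1
Anterior cingulate area	L	-0.102	1	-0.198	0
Anterior cingulate area	R	-0.113	1	-0.267	1
Bed nucleus of stria terminalis	L	0.466	1	0.918	1
Bed nucleus of stria terminalis	R	0.360	1	0.971	1
Caudoputamen	L	0.093	0	-0.224	1
Caudoputamen	R	0.059	0	-0.188	1
Cerebellar cortex	L	0.430	1	-0.268	1
Cerebellar cortex	R	0.478	1	-0.250	1
Dentate gyrus, molecular layer	L	-0.029	0	0.247	1
Dentate gyrus, molecular layer	R	0.041	0	0.232	1
CA1	L	0.151	1	0.385	1
CA1	R	0.109	0	0.377	1
CA3	L	0.004	0	0.307	1
CA3	R	0.004	0	0.411	1
Entorhinal cortex	L	0.470	1	-0.090	0
Entorhinal cortex	R	0.567	1	-0.138	0
Globus pallidus	L	0.154	1	0.112	1
Globus pallidus	R	0.138	1	0.180	1
Hippocampus	L	0.120	1	0.353	1
Hippocampus	R	0.129	1	0.379	1
Hypothalamus	L	0.631	1	0.185	1
Hypothalamus	R	0.617	1	0.109	1
Medial amygdalar nucleus	L	0.253	1	0.906	1
Medial amygdalar nucleus	R	0.183	1	1.034	1
Medial preoptic area	L	0.636	1	0.435	1
Medial preoptic area	R	0.680	1	0.367	1
Nucleus accumbens	L	-0.311	1	-0.005	0
Nucleus accumbens	R	-0.249	1	0.032	0
Perirhinal area	L	0.033	0	-0.120	0
Perirhinal area	R	0.086	0	-0.108	0
Piriform cortex	L	0.460	0	-0.131	0
Piriform cortex	R	0.756	1	-0.151	0
Posterior parietal association areas	L	-0.254	1	0.016	0
Posterior parietal association areas	R	-0.263	1	0.039	0
Primary auditory area	L	-0.163	0	-0.256	1
Primary auditory area	R	-0.182	1	-0.209	1
Primary motor area	L	-0.124	0	-0.329	1
Primary motor area	R	-0.081	0	-0.357	1
Primary somatosensory area	L	-0.237	1	-0.419	1
Primary somatosensory area	R	-0.219	1	-0.241	1
Primary visual area	L	0.175	1	0.029	0
Primary visual area	R	0.199	1	-0.102	0
Retrosplenial area	L	0.198	1	0.004	0
Retrosplenial area	R	0.182	1	0.035	0
Subiculum	L	0.182	1	0.317	1
Subiculum	R	-0.031	0	0.338	1
Temporal association areas	L	0.057	0	0.085	0
Temporal association areas	R	0.042	0	-0.004	0
Thalamus	L	-0.028	0	-0.098	0
Thalamus	R	-0.060	0	-0.139	1
Ventral orbital area	L	0.083	0	-0.209	1
Ventral orbital area	R	-0.046	0	-0.171	0
Brain stem	M	0.349	1	0.200	1
Medulla	M	0.385	1	0.204	1
Midbrain	M	0.423	1	0.191	1
Pons	M	0.279	1	0.065	0
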