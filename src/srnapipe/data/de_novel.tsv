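mirna_id	log2fc	direction	adj_p
novel_mir_70	15.60	up	0.00e+00
novel_mir_48	7.87	up	1.05e-08
novel_mir_71	7.22	up	8.78e-06
novel_mir_62	7.00	up	4.72e-05
novel_mir_63	6.92	up	8.27e-05
novel_mir_54	6.83	up	1.45e-04
novel_mir_60	6.73	up	2.54e-04
novel_mir_43	4.32	up	1.47e-130
novel_mir_36	-16.30	down	0.00e+00
novel_mir_31	-7.63	down	1.66e-08
novel_mir_18	-7.41	down	2.10e-07
novel_mir_14	-7.05	down	6.18e-06
novel_mir_38	-7.05	down	6.18e-06
novel_mir_3	-6.94	down	1.44e-05
novel_mir_4	-6.70	down	7.82e-05
novel_mir_30	-1.41	down	2.01e-02
novel_mir_25	-1.32	down	3.27e-02
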