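mirna_id	log2fc	direction	adj_p
hsa-miR-934	10.81	up	2.80e-62
hsa-miR-1269a	8.00	up	1.95e-09
hsa-miR-671-5p	7.15	up	1.54e-05
hsa-miR-663a	7.00	up	4.72e-05
hsa-miR-1292	4.72	up	5.30e-22
hsa-miR-615-5p	4.55	up	8.00e-56
hsa-miR-2276	4.50	up	8.08e-07
hsa-miR-1307-3p	3.50	up	0.00e+00
hsa-miR-3654	3.11	up	6.82e-08
hsa-miR-4741	2.70	up	1.98e-04
hsa-miR-100-5p	2.53	up	7.79e-04
hsa-miR-3189-3p	2.53	up	1.23e-06
hsa-miR-548t-5p	2.51	up	6.42e-12
hsa-miR-769-3p	2.25	up	4.12e-09
hsa-miR-1307-5p	2.09	up	1.08e-105
hsa-miR-3687	2.05	up	3.22e-04
hsa-miR-324-5p	2.02	up	1.36e-51
hsa-miR-449c-5p	1.74	up	7.67e-06
hsa-miR-532-5p	1.51	up	3.50e-16
hsa-miR-122-5p	1.35	up	7.26e-04
hsa-miR-301b	1.30	up	1.84e-03
hsa-miR-652-3p	1.23	up	2.34e-13
hsa-miR-181a-5p	1.23	up	0.00e+00
hsa-miR-140-3p	1.18	up	0.00e+00
hsa-miR-331-3p	1.03	up	1.83e-22
hsa-miR-10a-5p	1.00	up	0.00e+00
hsa-miR-3656	-6.94	down	1.44e-05
hsa-miR-146a-5p	-4.58	down	2.48e-06
hsa-miR-1246	-3.64	down	3.18e-292
hsa-miR-143-3p	-3.50	down	3.27e-05
hsa-miR-23a-5p	-2.50	down	4.30e-31
hsa-miR-4508	-2.37	down	1.67e-16
hsa-miR-4488	-2.27	down	3.64e-22
hsa-miR-548o-3p	-2.09	down	2.26e-03
hsa-miR-29c-5p	-2.07	down	9.01e-04
hsa-miR-21-3p	-1.90	down	5.29e-97
hsa-miR-215	-1.85	down	0.00e+00
hsa-miR-139-3p	-1.64	down	3.27e-11
hsa-miR-720	-1.56	down	5.01e-03
hsa-miR-3141	-1.45	down	5.75e-07
hsa-miR-29b-1-5p	-1.43	down	2.20e-07
hsa-miR-141-5p	-1.41	down	9.27e-03
hsa-miR-25-5p	-1.29	down	0.00e+00
hsa-miR-197-5p	-1.27	down	1.24e-08
hsa-miR-1260b	-1.19	down	4.47e-10
hsa-miR-22-5p	-1.17	down	4.87e-14
hsa-miR-628-5p	-1.06	down	1.42e-03
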