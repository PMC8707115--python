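label	mean_TL	sd_TL	mean_L	sd_L	mean_S	sd_S	mean_RL	sd_RL	mean_r	sd_r	classification
1	8.79	3.04	4.78	1.71	4.01	1.37	15.70	0.35	1.19	0.13	Metacentric
(1)	8.37	3.03	4.48	1.6	3.89	1.46	14.89	0.64	1.16	0.13	Metacentric
2	4.82	1.57	2.82	1.00	1.99	0.57	8.66	0.37	1.40	0.13	Metacentric
(2)	4.64	1.52	2.64	0.89	2.00	0.64	8.34	0.35	1.32	0.12	Metacentric
3	8.02	3.03	4.97	1.73	3.05	1.38	14.19	0.87	1.70	0.28	Submetacentric
(3)	7.76	2.98	4.87	1.97	2.99	1.03	13.70	0.91	1.61	0.23	Submetacentric
4	6.90	2.16	4.90	1.62	2.00	0.58	12.47	1.04	2.45	0.36	Submetacentric
(4)	6.67	2.14	4.65	1.50	2.03	0.66	12.05	0.90	2.29	0.20	Submetacentric
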