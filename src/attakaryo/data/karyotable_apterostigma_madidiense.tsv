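label	mean_TL	sd_TL	mean_L	sd_L	mean_S	sd_S	mean_RL	sd_RL	mean_r	sd_r	classification
1	6.95	1.32	3.73	0.81	3.22	0.52	6.74	0.25	1.17	0.09	Metacentric
(1)	6.58	1.21	3.54	0.69	3.06	0.57	6.39	0.24	1.17	0.07	Metacentric
2	5.75	1.12	3.13	0.63	2.62	0.46	5.58	0.23	1.19	0.07	Metacentric
(2)	5.39	1.05	2.92	0.54	2.45	0.52	5.22	0.18	1.20	0.13	Metacentric
3	5.01	0.89	2.77	0.44	2.24	0.48	4.87	0.15	1.26	0.18	Metacentric
(3)	4.82	0.86	2.79	0.49	2.03	0.39	4.68	0.13	1.38	0.18	Metacentric
4	4.71	0.82	2.61	0.43	2.09	0.53	4.58	0.12	1.36	0.16	Metacentric
(4)	4.60	0.79	2.63	0.41	1.97	0.56	4.47	0.09	1.48	0.15	Metacentric
5	4.50	0.74	2.54	0.32	1.94	0.44	4.38	0.08	1.35	0.19	Metacentric
(5)	4.38	0.72	2.54	0.35	1.83	0.41	4.26	0.07	1.42	0.21	Metacentric
6	4.31	0.73	2.56	0.40	1.73	0.36	4.19	0.07	1.50	0.17	Metacentric
(6)	4.25	0.71	2.36	0.47	1.86	0.47	4.14	0.07	1.43	0.25	Metacentric
7	4.20	0.71	2.47	0.32	1.75	0.42	4.09	0.07	1.45	0.22	Metacentric
(7)	4.12	0.72	2.36	0.38	1.77	0.38	4.01	0.10	1.35	0.20	Metacentric
8	4.02	0.69	2.29	0.40	1.72	0.35	3.91	0.08	1.35	0.21	Metacentric
(8)	3.84	0.62	2.09	0.50	1.75	0.22	3.74	0.12	1.31	0.19	Metacentric
9	3.64	0.61	2.06	0.34	1.57	0.29	3.54	0.17	1.33	0.15	Metacentric
(9)	3.48	0.54	1.96	0.31	1.53	0.27	3.40	0.14	1.30	0.19	Metacentric
10	3.35	0.52	1.94	0.33	1.42	0.24	3.27	0.10	1.38	0.19	Metacentric
(10)	3.22	0.46	1.83	0.30	1.40	0.23	3.15	0.13	1.32	0.23	Metacentric
11	3.12	0.46	1.81	0.21	1.31	0.27	3.05	0.12	1.41	0.18	Metacentric
(11)	3.06	0.47	1.83	0.28	1.23	0.20	2.98	0.11	1.50	0.12	Metacentric
12	2.82	0.48	1.63	0.31	1.20	0.19	2.76	0.22	1.36	0.18	Metacentric
(12)	2.64	0.33	1.53	0.20	1.12	0.14	2.59	0.19	1.36	0.13	Metacentric
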