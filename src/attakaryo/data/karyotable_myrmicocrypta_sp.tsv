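label	mean_TL	sd_TL	mean_L	sd_L	mean_S	sd_S	mean_RL	sd_RL	mean_r	sd_r	classification
1	4.27	0.88	2.37	0.44	1.89	0.46	5.20	0.18	1.28	0.15	Metacentric
(1)	4.14	0.89	2.27	0.44	1.87	0.46	5.03	0.15	1.23	0.13	Metacentric
2	3.96	0.83	2.24	0.49	1.72	0.38	4.82	0.18	1.32	0.16	Metacentric
(2)	3.89	0.81	2.12	0.46	1.77	0.37	4.73	0.17	1.21	0.10	Metacentric
3	3.76	0.89	2.07	0.57	1.69	0.38	4.54	0.20	1.23	0.22	Metacentric
(3)	3.68	0.89	1.99	0.49	1.69	0.43	4.44	0.18	1.19	0.14	Metacentric
4	3.44	0.79	1.95	0.50	1.49	0.31	4.16	0.14	1.30	0.13	Metacentric
(4)	3.30	0.75	1.83	0.39	1.47	0.37	4.00	0.12	1.26	0.10	Metacentric
5	3.22	0.71	1.79	0.38	1.43	0.34	3.91	0.11	1.26	0.11	Metacentric
(5)	3.14	0.71	1.70	0.34	1.43	0.37	3.80	0.09	1.21	0.11	Metacentric
6	3.06	0.69	1.69	0.37	1.37	0.34	3.70	0.10	1.25	0.15	Metacentric
(6)	2.99	0.65	1.68	0.37	1.31	0.31	3.63	0.06	1.29	0.13	Metacentric
7	2.90	0.63	1.62	0.35	1.28	0.31	3.51	0.08	1.28	0.14	Metacentric
(7)	2.86	0.64	1.57	0.31	1.29	0.33	3.46	0.07	1.24	0.12	Metacentric
8	2.80	0.64	1.57	0.35	1.24	0.31	3.39	0.06	1.29	0.14	Metacentric
(8)	2.73	0.62	1.54	0.34	1.20	0.29	3.31	0.10	1.30	0.14	Metacentric
9	2.65	0.63	1.47	0.31	1.17	0.32	3.20	0.14	1.28	0.16	Metacentric
(9)	2.56	0.63	1.41	0.33	1.15	0.31	3.09	0.16	1.25	0.17	Metacentric
10	2.41	0.57	1.39	0.29	1.01	0.30	2.91	0.17	1.42	0.20	Metacentric
(10)	2.20	0.55	1.22	0.31	0.97	0.30	2.65	0.20	1.37	0.16	Metacentric
11	1.94	0.48	1.11	0.27	0.82	0.25	2.33	0.11	1.43	0.17	Metacentric
(11)	1.84	0.44	1.06	0.26	0.79	0.20	2.22	0.10	1.36	0.17	Metacentric
12	1.70	0.39	0.98	0.22	0.72	0.18	2.06	0.11	1.38	0.13	Metacentric
(12)	1.62	0.38	0.93	0.21	0.69	0.17	1.95	0.09	1.35	0.13	Metacentric
13	3.57	0.82	2.39	0.53	1.17	0.31	4.34	0.46	2.07	0.26	Submetacentric
(13)	3.26	0.85	2.19	0.53	1.07	0.31	3.99	0.63	2.08	0.11	Submetacentric
14	2.36	0.50	1.67	0.39	0.70	0.12	2.88	0.20	2.38	0.30	Submetacentric
(14)	2.22	0.43	1.52	0.31	0.70	0.15	2.72	0.22	2.18	0.30	Submetacentric
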