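label	mean_TL	sd_TL	mean_L	sd_L	mean_S	sd_S	mean_RL	sd_RL	mean_r	sd_r	classification
1	3.19	1.40	1.76	0.73	1.43	0.68	3.84	0.2	1.27	0.14	Metacentric
(1)	2.91	1.29	1.71	0.76	1.20	0.55	3.50	0.22	1.45	0.22	Metacentric
2	2.62	1.06	1.40	0.62	1.22	0.47	3.18	0.18	1.18	0.12	Metacentric
(2)	2.48	1.09	1.31	0.62	1.17	0.50	2.98	0.23	1.28	0.16	Metacentric
3	2.39	1.04	1.28	0.53	1.10	0.52	2.87	0.24	1.22	0.17	Metacentric
(3)	2.23	0.94	1.31	0.53	0.92	0.43	2.69	0.21	1.44	0.22	Metacentric
4	2.13	0.92	1.26	0.59	0.86	0.33	2.56	0.14	1.44	0.20	Metacentric
(4)	2.08	0.89	1.18	0.5	0.90	0.40	2.51	0.10	1.36	0.19	Metacentric
5	2.00	0.84	1.13	0.43	0.88	0.43	2.42	0.09	1.34	0.26	Metacentric
(5)	1.89	0.71	1.10	0.42	0.79	0.30	2.32	0.14	1.40	0.13	Metacentric
6	1.83	0.67	1.03	0.37	0.80	0.33	2.24	0.12	1.32	0.23	Metacentric
(6)	1.80	0.65	0.97	0.31	0.82	0.36	2.20	0.11	1.26	0.13	Metacentric
7	1.75	0.65	0.97	0.37	0.79	0.28	2.15	0.10	1.25	0.16	Metacentric
(7)	1.72	0.63	0.95	0.35	0.77	0.30	2.11	0.08	1.34	0.12	Metacentric
8	1.68	0.63	0.98	0.33	0.72	0.29	2.05	0.11	1.39	0.14	Metacentric
(8)	1.66	0.62	0.94	0.37	0.72	0.27	2.03	0.11	1.36	0.18	Metacentric
9	1.62	0.60	0.95	0.38	0.68	0.26	1.99	0.08	1.42	0.22	Metacentric
(9)	1.59	0.60	0.91	0.37	0.68	0.26	1.95	0.10	1.42	0.18	Metacentric
10	1.55	0.60	0.89	0.36	0.66	0.25	1.89	0.08	1.33	0.13	Metacentric
(10)	1.54	0.60	0.85	0.30	0.69	0.29	1.88	0.07	1.27	0.13	Metacentric
11	1.52	0.56	0.82	0.28	0.70	0.28	1.86	0.08	1.21	0.15	Metacentric
(11)	1.48	0.55	0.83	0.30	0.66	0.25	1.82	0.07	1.26	0.08	Metacentric
12	1.45	0.50	0.85	0.31	0.60	0.20	1.79	0.10	1.43	0.16	Metacentric
(12)	1.41	0.50	0.81	0.28	0.60	0.22	1.74	0.10	1.38	0.14	Metacentric
13	1.38	0.49	0.78	0.26	0.59	0.24	1.69	0.08	1.37	0.21	Metacentric
(13)	1.37	0.49	0.77	0.25	0.59	0.24	1.68	0.08	1.34	0.15	Metacentric
14	1.34	0.49	0.75	0.28	0.59	0.21	1.64	0.09	1.28	0.10	Metacentric
(14)	1.27	0.44	0.76	0.29	0.51	0.16	1.56	0.11	1.46	0.14	Metacentric
15	2.72	1.32	1.90	0.95	0.82	0.38	3.29	0.73	2.28	0.19	Submetacentric
(15)	2.58	1.20	1.80	0.84	0.78	0.37	3.14	0.71	2.33	0.28	Submetacentric
16	2.60	1.00	1.80	0.67	0.80	0.33	3.18	0.15	2.27	0.17	Submetacentric
(16)	2.49	0.93	1.75	0.69	0.74	0.25	3.06	0.14	2.32	0.21	Submetacentric
17	2.43	0.94	1.69	0.64	0.75	0.31	2.97	0.07	2.27	0.18	Submetacentric
(17)	2.34	0.98	1.62	0.65	0.72	0.33	2.84	0.09	2.29	0.15	Submetacentric
18	2.18	0.95	1.48	0.62	0.71	0.33	2.64	0.16	2.11	0.16	Submetacentric
(18)	2.13	0.94	1.47	0.68	0.66	0.26	2.56	0.15	2.21	0.25	Submetacentric
19	2.04	0.93	1.39	0.59	0.65	0.35	2.45	0.17	2.19	0.21	Submetacentric
(19)	2.00	0.90	1.35	0.61	0.66	0.30	2.41	0.18	2.07	0.21	Submetacentric
20	1.91	0.78	1.27	0.50	0.64	0.29	2.32	0.11	2.01	0.16	Submetacentric
(20)	1.82	0.76	1.24	0.54	0.59	0.23	2.21	0.17	2.08	0.26	Submetacentric
21	1.64	0.75	1.10	0.52	0.54	0.23	1.99	0.25	2.02	0.17	Submetacentric
(21)	1.52	0.75	1.03	0.55	0.50	0.20	1.83	0.22	2.00	0.21	Submetacentric
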