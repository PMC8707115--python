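taxon	diploid_2n	haploid_n	gs_1c_pg	locality	country	karyotype	karyotype_alt	hc_C	hc_PC	hc_IN	hc_SA	hc_LA	reference	new_report
Acromyrmex ambiguus	38		0.33	SP	Uruguay	14 m + 12 sm + 8 st + 4 a	2 m + 6 sm + 16 st + 14 a	+	+	-	+	-	B28;B29	0
Acromyrmex ameliae	36			MG	Brazil	10 m + 16 sm + 8 st + 2 a		+	-	-	+	-	B30	0
Acromyrmex aspersus	38			MG	Brazil	8 m + 10 sm + 16 st + 4 a							B31	0
Acromyrmex balzani	38		0.37	MG	Brazil, French Guiana	12 m + 10 sm + 14 st + 2 a		+	+	-	+	-	B32;B33	0
Acromyrmex coronatus	38	19	0.34	MG	Brazil	12 m + 8 sm + 16 st + 2 a		+	+	-	+	-	B32	0
Acromyrmex crassispinus	38		0.34	MG	Brazil	12 m + 20 sm + 4 st + 2 a							B29;B34	0
Acromyrmex disciger	38		0.33	MG	Brazil	10 m + 12 sm + 14 st + 2 a		+	+	-	+	-	B32	0
Acromyrmex echinatior	38		0.36		Panama	8 m + 6 sm + 14 st + 10 a		-	-	+	+	-	B32	0
Acromyrmex heyeri	38			RS	Uruguay, Brazil	2 m + 6 sm + 16 st + 14 a							B28;B35	0
Acromyrmex hispidus	38				Uruguay	2 m + 6 sm + 16 st + 14 a							B28	0
Acromyrmex lundi	38	19		RS	Brazil	10 m + 14 sm + 10 st + 4 a							B29	0
Acromyrmex niger	38		0.36	MG	Brazil	12 m + 14 sm + 10 st + 2 a		-	+	-	+	-	B32	0
Acromyrmex nigrosetosus	38	19	0.35	MG	Brazil	12 m + 14 sm + 10 st + 2 a							B29	0
Acromyrmex rugosus	38		0.35	MG	Brazil	16 m + 12 sm + 8 st + 2 a		+	+	-	+	-	B32	0
Acromyrmex subterraneus molestans	38		0.34	MG	Brazil	10 m + 10 sm + 16 st + 2 a							B31;B34	0
Acromyrmex subterraneus subterraneus	38		0.35	MG	Brazil	14 m + 18 sm + 4 st + 2 a		+	+	-	+	-	B29;B34	0
Acromyrmex subterraneus brunneus	38		0.34	MG	Brazil	10 m + 14 sm + 12 st + 2 a		+	-	-	+	-	B30	0
Amoimyrmex striatus	22		0.35	SC	Brazil	20 m + 2 sm		+	+	-	+	-	B11	0
Amoimyrmex silvestrii	22				Argentine	20 m + 2 sm							B36	0
Amoimyrmex bruchi	22				Argentine	20 m + 2 sm							B36	0
Apterostigma madidiense		23			Brazil	14 m + 20 sm + 10 st + 2 a							B37	0
Apterostigma madidiense	24		0.74	MG	Brazil	24 m		+	+	-	-	-	This study	1
Apterostigma mayri	24				Panama	24 m		+	-	-	-	-	B38	0
Apterostigma sp.	20				Brazil	6 m + 12 sm + 2 a							B34	0
Apterostigma sp.	24				Panama	24 m							B38	0
Apterostigma sp.	32				French Guiana	14 m + 6 sm + 10 st + 2 t							B39	0
Apterostigma steigeri	22				Brazil	20 m + 2 sm							B37	0
Atta bisphaerica	22			MG	Brazil	12 m + 6 sm + 4 a		+	+	-	-	-	B34;B40	0
Atta colombica	22	11	0.31		Panama	12 m + 6 sm + 4 a		+	-	+	-	-	B38	0
Atta laevigata	22		0.33	MG	Brazil	12 m + 6 sm + 4 a		+	+	-	-	-	B34;B40	0
Atta robusta	22		0.34	ES	Brazil	18 m + 2 sm + 2 st		+	+	-	-	-	B41	0
Atta sexdens	22		0.33	MG, RS	Brazil	12 m + 6 sm + 4 a		+	+	-	-	-	B34;B35;B40	0
Atta sexdens	22				French Guiana	18 m + 2 sm + 2 st		+	+	-	-	-	B33	0
Cyphomyrmex cornutus	22				French Guiana	10 m + 12 sm							B39	0
Cyphomyrmex costatus	20				Panama	20 m		+	-	-	-	-	B38	0
Cyphomyrmex rimosus	32				Panama	28 m + 4 a							B38	0
Cyphomyrmex transversus	24	12			French Guiana	14 m + 6 sm + 4 a							B33	0
Cyphomyrmex transversus	42	21	0.50	RJ	Brazil	28 m + 14 sm		+	-	-	-	-	This study	1
Mycetarotes carinatus	14			MG	Brazil	8 m + 6 sm		+	+	-	-	-	B42	0
Mycetarotes parallelus	54		0.38	MG	Brazil	26 m + 16 sm + 6 a		+	+	-	+	-	B42	0
Mycetomoellerius fuscus	18	9	0.47	MG	Brazil	16 m + 2 sm		+	+	-	-	-	B43	0
Mycetomoellerius holmgreni	20	10	0.33	MG, SC, RS	Brazil	20 m		+	+	-	-	-	B7	0
Mycetomoellerius iheringi	20	10	0.40	SC	Brazil	18 m + 2 sm		+	+	-	-	-	B44	0
Mycetomoellerius relictus	20	10		MG	Brazil	20 m		+	+	-	-	-	B37	0
Mycetomoellerius sp.	22			MG	Brazil	18 m + 4 sm							B37	0
Mycetophylax conformis	30	15	0.31	RJ, SP	Brazil	22 m + 8 sm		+	+	-	+	-	B10	0
Mycetophylax morschi	30	15	0.34	RJ, RS, SC	Brazil	18 m + 6 sm + 2 a		+	-	-	-	-	B10	0
Mycetophylax morschi	26	13	0.31	SC	Brazil	18 m + 10 sm + 2 a		+	-	-	-	-	B10	0
Mycetophylax morschi	28	14		BA	Brazil	18 m + 10 sm		+	-	-	-	-	B17	0
Mycetophylax simplex	36	18	0.41	SC, PR, SP	Brazil	20 m + 16 sm		+	+	-	+	-	B10	0
Mycocepurus goeldii	8			MG	Brazil	8 m		+	+	-	-	-	B45	0
Mycocepurus goeldii	8	4	0.42	SC	Brazil	4 m + 4 sm							This study	1
Mycocepurus sp.	8				Panama	4 m							B38	0
Myrmicocrypta sp.	30				French Guiana	22 m + 2 sm + 6 a							B33	0
Myrmicocrypta sp.	28	14	0.48	RJ	Brazil	24 m + 4 sm		+	+	-	-	-	This study	1
Sericomyrmex amabilis	50		0.45		Panama	50 m		+	+	-	-	-	B38	0
Sericomyrmex sp.	50	25		MG	Brazil	44 m + 6 sm							B37	0
Serycomyrmex parvulus	50	25	0.42	MG	Brazil	30 m + 14 sm + 6 st		+	+	-	-	-	This study	1
Trachymyrmex septentrionalis	20	10	0.25		Panama	20 m							B38	0
Trachymyrmex sp.1	12	6			Panama	12 m		+	-	+	-	-	B38	0
Trachymyrmex sp.2	18				Panama	18 m							B38	0
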