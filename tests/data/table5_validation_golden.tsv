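taxon	source	status
Acromyrmex ambiguus	B28;B29	diploid_consistent
Acromyrmex ameliae	B30	diploid_consistent
Acromyrmex aspersus	B31	diploid_consistent
Acromyrmex balzani	B32;B33	diploid_consistent
Acromyrmex coronatus	B32	diploid_consistent
Acromyrmex crassispinus	B29;B34	diploid_consistent
Acromyrmex disciger	B32	diploid_consistent
Acromyrmex echinatior	B32	diploid_consistent
Acromyrmex heyeri	B28;B35	diploid_consistent
Acromyrmex hispidus	B28	diploid_consistent
Acromyrmex lundi	B29	diploid_consistent
Acromyrmex niger	B32	diploid_consistent
Acromyrmex nigrosetosus	B29	diploid_consistent
Acromyrmex rugosus	B32	diploid_consistent
Acromyrmex subterraneus molestans	B31;B34	diploid_consistent
Acromyrmex subterraneus subterraneus	B29;B34	diploid_consistent
Acromyrmex subterraneus brunneus	B30	diploid_consistent
Amoimyrmex striatus	B11	diploid_consistent
Amoimyrmex silvestrii	B36	diploid_consistent
Amoimyrmex bruchi	B36	diploid_consistent
Apterostigma madidiense	B37	diploid_consistent
Apterostigma madidiense	This study	diploid_consistent
Apterostigma mayri	B38	diploid_consistent
Apterostigma sp.	B34	diploid_consistent
Apterostigma sp.	B38	diploid_consistent
Apterostigma sp.	B39	diploid_consistent
Apterostigma steigeri	B37	diploid_consistent
Atta bisphaerica	B34;B40	diploid_consistent
Atta colombica	B38	diploid_consistent
Atta laevigata	B34;B40	diploid_consistent
Atta robusta	B41	diploid_consistent
Atta sexdens	B34;B35;B40	diploid_consistent
Atta sexdens	B33	diploid_consistent
Cyphomyrmex cornutus	B39	diploid_consistent
Cyphomyrmex costatus	B38	diploid_consistent
Cyphomyrmex rimosus	B38	diploid_consistent
Cyphomyrmex transversus	B33	diploid_consistent
Cyphomyrmex transversus	This study	diploid_consistent
Mycetarotes carinatus	B42	diploid_consistent
Mycetarotes parallelus	B42	inconsistent
Mycetomoellerius fuscus	B43	diploid_consistent
Mycetomoellerius holmgreni	B7	diploid_consistent
Mycetomoellerius iheringi	B44	diploid_consistent
Mycetomoellerius relictus	B37	diploid_consistent
Mycetomoellerius sp.	B37	diploid_consistent
Mycetophylax conformis	B10	diploid_consistent
Mycetophylax morschi	B10	inconsistent
Mycetophylax morschi	B10	inconsistent
Mycetophylax morschi	B17	diploid_consistent
Mycetophylax simplex	B10	diploid_consistent
Mycocepurus goeldii	B45	diploid_consistent
Mycocepurus goeldii	This study	diploid_consistent
Mycocepurus sp.	B38	haploid_consistent
Myrmicocrypta sp.	B33	diploid_consistent
Myrmicocrypta sp.	This study	diploid_consistent
Sericomyrmex amabilis	B38	diploid_consistent
Sericomyrmex sp.	B37	diploid_consistent
Sericomyrmex parvulus	This study	diploid_consistent
Trachymyrmex septentrionalis	B38	diploid_consistent
Trachymyrmex sp.1	B38	diploid_consistent
Trachymyrmex sp.2	B38	diploid_consistent
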