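((('Mycocepurus goeldii':10,'Mycocepurus sp.':10):40,('Myrmicocrypta sp.':48,('Apterostigma steigeri':45,('Apterostigma mayri':20,'Apterostigma madidiense':20):25):3):2):11,(('Mycetophylax simplex':20,('Mycetophylax conformis':10,'Mycetophylax morschi':10):10):30,(('Mycetarotes carinatus':15,'Mycetarotes parallelus':15):30,((('Cyphomyrmex costatus':19,'Cyphomyrmex rimosus':19):6,('Cyphomyrmex cornutus':15,'Cyphomyrmex transversus':15):10):15,((('Trachymyrmex septentrionalis':16.8,('Trachymyrmex sp.1':10,'Trachymyrmex sp.2':10):6.8):13.2,(('Sericomyrmex amabilis':5,'Sericomyrmex parvulus':5):23,('Mycetomoellerius fuscus':24.8,('Mycetomoellerius relictus':15,('Mycetomoellerius holmgreni':8,'Mycetomoellerius iheringi':8):7):9.8):3.2):2):5,(('Amoimyrmex striatus':4.7,('Amoimyrmex silvestrii':2,'Amoimyrmex bruchi':2):2.7):21.3,(('Atta robusta':13.7,(('Atta bisphaerica':5,'Atta laevigata':5):5,('Atta sexdens':7,'Atta colombica':7):3):3.7):4.3,('Acromyrmex balzani':10,('Acromyrmex coronatus':8,('Acromyrmex lundi':5,'Acromyrmex echinatior':5):3):2):8):8):9):5):5):5):11):0.0;
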