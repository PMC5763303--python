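# Curated ingredient entries with antineoplastic / anti-inflammatory role assignments.
# One line per entry; the drug column lists every drug the entry is assigned to.
drug	category	fact_type	organism_id	anatomy_id	chemical_label	chemical_id	roles	ae_label	ae_id
Common Floweringqince Fruit	anti-rheumatism TCD	chemical			4-terpineol	CHEBI_78884	anti-inflammatory;antineoplastic
Silk-worm Droppings;Tiger Bone	anti-rheumatism TCD	chemical			all-trans-retinoic acid	CHEBI_15367	anti-inflammatory;antineoplastic
Chinese Clematis Root;Common Floweringqince Fruit	anti-rheumatism TCD	chemical			botulin	CHEBI_3086	anti-inflammatory;antineoplastic
Chinese Taxillus Herb;Common Floweringqince Fruit;Debark Peony Root	anti-rheumatism TCD	chemical			betulinic acid	CHEBI_3087	anti-inflammatory;antineoplastic
Common Threewingnut Root;Tripterygii Hypoglauci Radix	anti-rheumatism TCD	chemical			celastrol	CHEBI_63959	anti-inflammatory;antineoplastic
Nux Vomica	anti-rheumatism TCD	chemical			ethyl trans-caffeate	CHEBI_132714	anti-inflammatory;antineoplastic
Fourstamen Stephania Root	anti-rheumatism TCD	chemical			fangchinoline	CHEBI_132893	anti-inflammatory;antineoplastic
Common Threewingnut Root	anti-rheumatism TCD	chemical			tripdiolide	CHEBI_9740	anti-inflammatory;antineoplastic
Common Threewingnut Root;Tripterygii Hypoglauci Radix	anti-rheumatism TCD	chemical			triptolide	CHEBI_9747	anti-inflammatory;antineoplastic
Acanthopanax Root Bark	anti-rheumatism TCD	chemical			(+)-sesamin	CHEBI_66470	antineoplastic
Common Threewingnut Root	anti-rheumatism TCD	chemical			(+)-syringaresinol	CHEBI_47	antineoplastic
Acanthopanax Root Bark;Chinese Taxillus Herb;Common Floweringqince Fruit;Nux Vomica	anti-rheumatism TCD	chemical			3,4-dihydroxybenzoic acid	CHEBI_36062	antineoplastic
Chinese Starjasmine Stem;Harlequin Glorybower Leaf	anti-rheumatism TCD	chemical			apigenin	CHEBI_18388	antineoplastic
Wooly Datchmanspipe Herb	anti-rheumatism TCD	chemical			beta-elemene	CHEBI_62854	antineoplastic
Chinese Clematis Root	anti-rheumatism TCD	chemical			daidzein	CHEBI_28197	antineoplastic
Common Threewingnut Root	anti-rheumatism TCD	chemical			emodin	CHEBI_42223	antineoplastic
Common Floweringqince Fruit;Nux Vomica	anti-rheumatism TCD	chemical			gallic acid	CHEBI_30778	antineoplastic
Chinese Clematis Root	anti-rheumatism TCD	chemical			genistein	CHEBI_28088	antineoplastic
Chinese Clematis Root	anti-rheumatism TCD	chemical			hesperetin	CHEBI_28230	antineoplastic
Harlequin Glorybower Leaf	anti-rheumatism TCD	chemical			hydroxytyrosol	CHEBI_68889	antineoplastic
Largeleaf Gentian Root	anti-rheumatism TCD	chemical			isoorientin	CHEBI_17965	antineoplastic
Common Floweringqince Fruit;Chinese Starjasmine Stem	anti-rheumatism TCD	chemical			luteolin	CHEBI_15864	antineoplastic
Common Floweringqince Fruit	anti-rheumatism TCD	chemical			maslinic acid	CHEBI_66682	antineoplastic
Doubleteeth Pubescent Angelica Root	anti-rheumatism TCD	chemical			methoxsalen	CHEBI_18358	antineoplastic
Mulberry Twig	anti-rheumatism TCD	chemical			morin	CHEBI_75092	antineoplastic
Mulberry Ttwig	anti-rheumatism TCD	chemical			morusin	CHEBI_7005	antineoplastic
Chinese Starjasmine Stem	anti-rheumatism TCD	chemical			naringin	CHEBI_28819	antineoplastic
Chinese Clematis Root	anti-rheumatism TCD	chemical			neohesperidin	CHEBI_59016	antineoplastic
Chinese Clematis Root;Common Threewingnut Root	anti-rheumatism TCD	chemical			nobiletin	CHEBI_7602	antineoplastic
Tripterygii Hypoglauci Radix	anti-rheumatism TCD	chemical			procyanidin B4	CHEBI_27589	antineoplastic
Chinese Clematis Root;Common Floweringqince Fruit;Chinese Taxillus Herb	anti-rheumatism TCD	chemical			quercetin	CHEBI_16243	antineoplastic
Common Threewingnut Root	anti-rheumatism TCD	chemical			sciscllascilloside E-1	CHEBI_66439	antineoplastic
Common Threewingnut Root	anti-rheumatism TCD	chemical			triptonide	CHEBI_132267	antineoplastic
Harlequin Glorybower Leaf	anti-rheumatism TCD	chemical			acteoside	CHEBI_132853	anti-inflammatory
Common Floweringqince Fruit	anti-rheumatism TCD	chemical			decanoic acid	CHEBI_30813	anti-inflammatory
Chinese Taxillus Herb;Nux Vomica	anti-rheumatism TCD	chemical			ferulic acid	CHEBI_17620	anti-inflammatory
Chinese Taxillus Herb;Nux Vomica;Silk-worm Droppings	anti-rheumatism TCD	chemical			lupeol	CHEBI_6570	anti-inflammatory
Common Floweringqince Fruit	anti-rheumatism TCD	chemical			maslinic acid	CHEBI_66682	anti-inflammatory
Trypterygii Hypoglauci Radix	anti-rheumatism TCD	chemical			procyanidin B3	CHEBI_75630	anti-inflammatory
Chinese Clematis Root	anti-rheumatism TCD	chemical			tectorigenin	CHEBI_9429	anti-inflammatory
Common Threewingnut Root	anti-rheumatism TCD	chemical			triptonide	CHEBI_132267	anti-inflammatory
Tripterygii Hypoglauci Radix	anti-rheumatism TCD	chemical			fredelin	CHEBI_5171	anti-inflammatory
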