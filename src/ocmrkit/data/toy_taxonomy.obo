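format-version: 1.2

[Term]
id: NCBITaxon:2759
name: Eukaryota

[Term]
id: NCBITaxon:33213
name: Bilateria
is_a: NCBITaxon:2759

[Term]
id: NCBITaxon:32524
name: Amniota
is_a: NCBITaxon:33213

[Term]
id: NCBITaxon:50557
name: Insecta
is_a: NCBITaxon:33213

[Term]
id: NCBITaxon:9694
name: Panthera tigris
synonym: "tiger" EXACT []
is_a: NCBITaxon:32524

[Term]
id: NCBITaxon:91950
name: Ptyas dhumnades
synonym: "black-tail snake" EXACT []
is_a: NCBITaxon:32524

[Term]
id: NCBITaxon:7091
name: Bombyx mori
synonym: "silkworm" EXACT []
is_a: NCBITaxon:50557
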