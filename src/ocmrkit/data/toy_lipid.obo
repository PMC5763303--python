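format-version: 1.2

[Term]
id: CHEBI:18059
name: lipid

[Term]
id: CHEBI:26873
name: terpenoid
is_a: CHEBI:18059

[Term]
id: CHEBI:23849
name: diterpenoid
is_a: CHEBI:26873

[Term]
id: CHEBI:36615
name: triterpenoid
is_a: CHEBI:26873

[Term]
id: CHEBI:25872
name: pentacyclic triterpenoid
is_a: CHEBI:36615

[Term]
id: CHEBI:9740
name: tripdiolide
is_a: CHEBI:23849

[Term]
id: CHEBI:9747
name: triptolide
is_a: CHEBI:23849

[Term]
id: CHEBI:63959
name: celastrol
is_a: CHEBI:25872
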