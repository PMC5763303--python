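format-version: 1.2

[Term]
id: CHEBI:50906
name: role

[Term]
id: CHEBI:24432
name: biological role
is_a: CHEBI:50906

[Term]
id: CHEBI:33232
name: application
is_a: CHEBI:50906

[Term]
id: CHEBI:35610
name: antineoplastic agent
is_a: CHEBI:33232

[Term]
id: CHEBI:67079
name: anti-inflammatory agent
is_a: CHEBI:33232
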