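format-version: 1.2

[Term]
id: OAE:0000001
name: adverse event

[Term]
id: OAE:0000100
name: behavioral and neurological adverse event
is_a: OAE:0000001

[Term]
id: OAE:0000110
name: sensory capability adverse event
is_a: OAE:0000100

[Term]
id: OAE:0000200
name: digestive system adverse event
is_a: OAE:0000001

[Term]
id: OAE:0000300
name: skin adverse event
is_a: OAE:0000001

[Term]
id: OAE:0000111
name: dizziness adverse event
is_a: OAE:0000110

[Term]
id: OAE:0000112
name: paresthesia adverse event
is_a: OAE:0000110

[Term]
id: OAE:0000113
name: tinnitus adverse event
is_a: OAE:0000110

[Term]
id: OAE:0000114
name: blurred vision adverse event
is_a: OAE:0000110

[Term]
id: OAE:0000115
name: hearing loss adverse event
is_a: OAE:0000110

[Term]
id: OAE:0000116
name: taste change adverse event
is_a: OAE:0000110

[Term]
id: OAE:0000117
name: numbness adverse event
is_a: OAE:0000110

[Term]
id: OAE:0000101
name: headache adverse event
is_a: OAE:0000100

[Term]
id: OAE:0000201
name: nausea and vomiting adverse event
is_a: OAE:0000200

[Term]
id: OAE:0000202
name: anorexia adverse event
is_a: OAE:0000200

[Term]
id: OAE:0000203
name: abdominal pain adverse event
is_a: OAE:0000200

[Term]
id: OAE:0000301
name: rash adverse event
is_a: OAE:0000300

[Term]
id: OAE:0000302
name: pruritus adverse event
is_a: OAE:0000300
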