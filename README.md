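# ocmrkit

Ontology-backed knowledge graphs for curated traditional-drug annotations.

`ocmrkit` ingests a drug-centric curation table (drugs, source organisms and
anatomic parts, chemical ingredients with ChEBI ids and curator-assigned
roles, adverse events with OAE ids), merges it with ontology hierarchy slices
(OBO-flavored flat files), and materializes a knowledge graph whose
existential axioms (`has part`, `participates in`, `has role`) can be
serialized as OWL-style Turtle or queried as flattened N-Triples. On top of
that it provides:

- **ontology_model** — multi-parent `is_a` DAG with OBO reading/writing,
  ancestor/descendant closures and validation (cycles, dangling edges).
- **subset_extraction** — MIREOT-style minimal-hierarchy extraction with
  *computed intermediates*: the fixpoint of pairwise minimal common
  ancestors, with nearest-kept-ancestor edge contraction.
- **curation_ingest** — long-format TSV parsing, label normalization,
  per-drug and global validation tallies.
- **kg_builder** — deterministic drug-class minting, template-driven
  existential axiom generation, byte-stable Turtle / N-Triples export.
- **query_engine** — conjunctive triple-pattern matching (basic graph
  patterns with optional reflexive-transitive `is_a` closure).
- **role_analysis** — role-bearing chemical classification with subsumption
  on both the chemical and the role side; structural branch membership.
- **ae_analysis** — adverse-event uniqueness, cross-drug sharing histograms,
  top-level AE classification against an ontology slice.
- **synthetic_data** — seeded generators with a ground-truth ledger for
  end-to-end parameter-recovery testing.

A small transcription of the published per-role ingredient table (42 entries
over 19 drugs) and toy ontology slices ship under `src/ocmrkit/data/` so the
whole pipeline runs offline.

## CLI

```sh
ocmrkit ontology validate slice.obo
ocmrkit extract --obo slice.obo --seeds seeds.txt --mode computed --out subset.obo
ocmrkit curation validate table.tsv --ontology chebi=chebi_slice.obo
ocmrkit build --table table.tsv --ontology chebi=chebi_slice.obo \
    --out kg.ttl --materialized kg.nt
ocmrkit query --kg kg.nt --query query.yaml
ocmrkit roles --kg kg.nt --role CHEBI:67079 --role CHEBI:35610
ocmrkit branches --obo chebi_slice.obo --chemicals chems.txt --branch CHEBI:23849
ocmrkit ae --table table.tsv --oae oae_slice.obo --designated classes.txt
ocmrkit synth --params params.yaml --out-dir fixtures/
```

Query YAML lists basic graph patterns; `?x` marks variables:

```yaml
patterns:
  - {s: "?x", p: "RO:0000087", o: "CHEBI:35610"}
```

## Curation table format

Tab-separated, UTF-8, `#` comments; columns
`drug, category, fact_type, organism_id, anatomy_id, chemical_label,
chemical_id, roles, ae_label, ae_id`. Each row carries one fact
(`source`, `chemical` or `ae`); the `drug` column may list several
';'-separated drugs and expands to one row per drug; `roles` is a
';'-separated subset of `anti-inflammatory`/`antineoplastic`. Identifiers may
be written as `CHEBI:9747`, `CHEBI_9747` or full OBO PURLs.
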