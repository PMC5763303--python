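import random

import pytest

from ocmrkit.curation_ingest import CurationRow, CurationTable
from ocmrkit.fixtures import ANTINEOPLASTIC, chebi_role_slice, table1_kg, table1_table
from ocmrkit.kg_builder import (
    IS_A,
    AxiomTemplate,
    KGBuildError,
    RelationConfig,
    Triple,
    apply_template,
    build_kg,
    export_ntriples,
    export_turtle,
    mint_drug_term,
    mint_drug_terms,
    parse_ntriples,
)
from ocmrkit.ontology_model import TermId
from ocmrkit.synthetic_data import GeneratorParams, generate_dataset

RC = RelationConfig()


def one_chem_table() -> CurationTable:
    return CurationTable([
        CurationRow(
            drug_label="Drug A", drug_category="cat", fact_type="chemical",
            chemical_label="thing", chemical_id=TermId("CHEBI", "1"),
        )
    ])


# ----------------------------------------------------------------- minting


def test_first_label_gets_first_id():
    ids = mint_drug_terms(["beta drug", "Alpha Drug"], "OCMR")
    assert ids["alpha drug"] == TermId("OCMR", "0000001")
    assert ids["beta drug"] == TermId("OCMR", "0000002")


def test_minting_idempotent(table1):
    labels = [r.drug_label for r in table1.rows]
    assert mint_drug_terms(labels) == mint_drug_terms(list(reversed(labels)))


def test_minting_injective_over_fixture_drugs(table1):
    ids = mint_drug_terms(r.drug_label for r in table1.rows)
    assert len(set(ids.values())) == len(ids) == 19


def test_single_term_mint():
    t = mint_drug_term("Drug A", "OCMR", ["Drug A", "Drug B"])
    assert t == TermId("OCMR", "0000001")


def test_malformed_namespace_rejected():
    with pytest.raises(KGBuildError, match="namespace"):
        mint_drug_terms(["x"], "9BAD:NS")


# ---------------------------------------------------------------- templates


def test_has_part_template_single_row():
    result = apply_template(AxiomTemplate("{drug} has_part {chemical_id}"),
                            one_chem_table())
    assert result.skipped == 0
    assert result.triples == {
        Triple(TermId("OCMR", "0000001"), RC.has_part, TermId("CHEBI", "1"))
    }


def test_participates_in_template_skips_non_ae_rows(table1):
    result = apply_template(AxiomTemplate("{drug} participates_in {ae_id}"),
                            table1)
    assert result.triples == set()
    assert result.skipped == len(table1.rows)


def test_unknown_relation_name_errors():
    with pytest.raises(KGBuildError, match="unknown relation"):
        apply_template(AxiomTemplate("{drug} summons {chemical_id}"),
                       one_chem_table())


def test_template_counts_match_generator_truth():
    _, ct, truth = generate_dataset(GeneratorParams(seed=11))
    result = apply_template(AxiomTemplate("{drug} has_part {chemical_id}"), ct)
    planted_pairs = sum(len(v) for v in truth.drug_chemicals.values())
    assert len(result.triples) == planted_pairs


# -------------------------------------------------------------------- build


def test_empty_table_keeps_only_imported_triples():
    roles = chebi_role_slice()
    kg = build_kg(CurationTable([]), {"chebi": roles})
    assert len(kg.triples) == len(roles.is_a)
    assert all(t.axiom_kind == "is_a" for t in kg.triples)


def test_threewingnut_triptolide_has_part(table1):
    kg = build_kg(table1)
    drug = mint_drug_term("Common Threewingnut Root", "OCMR",
                          (r.drug_label for r in table1.rows))
    assert Triple(drug, RC.has_part, TermId("CHEBI", "9747")) in kg.triples


def test_table1_has_part_pair_count(table1):
    # 60 (drug, entry) mentions in the fixture minus the two duplicated
    # (drug, chemical) pairs (maslinic acid and triptonide re-listed under
    # the same drug in a second role section) = 58 distinct pairs
    kg = build_kg(table1)
    pairs = {(t.subject, t.object) for t in kg.matching(predicate=RC.has_part)}
    assert len(pairs) == 58


def test_curator_roles_become_has_role_triples(table1):
    kg = build_kg(table1)
    assert Triple(TermId("CHEBI", "9747"), RC.has_role, ANTINEOPLASTIC) in kg.triples


def test_drugs_classified_under_category(table1):
    kg = build_kg(table1)
    cat_triples = [t for t in kg.triples if t.axiom_kind == "is_a"
                   and t.subject.prefix == "OCMR"]
    assert len(cat_triples) == 19
    assert len({t.object for t in cat_triples}) == 1  # one shared category


def test_duplicate_drug_label_after_normalization_rejected():
    ct = CurationTable([
        CurationRow(drug_label="Drug A TCD", fact_type="chemical",
                    chemical_label="x", chemical_id=TermId("CHEBI", "1")),
        CurationRow(drug_label="drug  a", fact_type="chemical",
                    chemical_label="y", chemical_id=TermId("CHEBI", "2")),
    ])
    with pytest.raises(KGBuildError, match="duplicate drug label"):
        build_kg(ct)


def test_triple_count_arithmetic_identity():
    for seed in range(5):
        g, ct, truth = generate_dataset(
            GeneratorParams(seed=seed, ae_sharing_spec=((2, 3),))
        )
        kg = build_kg(ct, {"syn": g})
        imported = len(g.is_a) + len(g.cross_links)
        minted_is_a = len({r.drug_label for r in ct.rows})  # one category each
        chem_pairs = len({(r.drug_label, r.chemical_id)
                          for r in ct.rows_of("chemical")})
        ae_pairs = len({(r.drug_label, r.ae_id) for r in ct.rows_of("ae")})
        src = len({(r.drug_label, r.organism) for r in ct.rows_of("source")})
        role_triples = 0  # synthetic tables carry no curator roles
        assert len(kg.triples) == (
            imported + minted_is_a + chem_pairs + ae_pairs + src + role_triples
        )


def test_relation_config_rejects_duplicates():
    with pytest.raises(KGBuildError, match="duplicate"):
        RelationConfig(has_part=TermId("RO", "0000087"))


def test_relation_config_from_mapping_override():
    rc = RelationConfig.from_mapping(
        {"produced_by": {"curie": "RO:0001234", "label": "made from organism"}}
    )
    assert rc.produced_by == TermId("RO", "0001234")
    assert rc.labels["produced_by"] == "made from organism"
    assert rc.has_part == RC.has_part


# -------------------------------------------------------------- serializing


def test_empty_kg_turtle_has_prefixes_only(tmp_path):
    from ocmrkit.kg_builder import KnowledgeGraph

    out = tmp_path / "empty.ttl"
    export_turtle(KnowledgeGraph(), out)
    lines = [l for l in out.read_text().splitlines() if l.strip()]
    assert all(l.startswith("@prefix") for l in lines)


def test_single_triple_turtle_and_ntriples(tmp_path):
    from ocmrkit.kg_builder import KnowledgeGraph

    kg = KnowledgeGraph()
    kg.add(Triple(TermId("OCMR", "0000001"), RC.has_part, TermId("CHEBI", "9747")))
    ttl, nt = tmp_path / "kg.ttl", tmp_path / "kg.nt"
    export_turtle(kg, ttl)
    export_ntriples(kg, nt)
    assert ttl.read_text().count("owl:Restriction") == 1
    assert ttl.read_text().count("owl:someValuesFrom") == 1
    nt_lines = [l for l in nt.read_text().splitlines() if l.strip()]
    assert nt_lines == [
        "<http://purl.obolibrary.org/obo/OCMR_0000001> "
        "<http://purl.obolibrary.org/obo/BFO_0000051> "
        "<http://purl.obolibrary.org/obo/CHEBI_9747> ."
    ]


def test_ntriples_roundtrip(tmp_path, table1):
    kg = build_kg(table1, {"chebi": chebi_role_slice()})
    out = tmp_path / "kg.nt"
    export_ntriples(kg, out)
    kg2 = parse_ntriples(out)
    assert kg2.triples == kg.triples
    assert kg2.labels == kg.labels


def test_serialization_is_deterministic(tmp_path):
    paths = []
    for i in range(2):
        kg = table1_kg()
        ttl = tmp_path / f"kg{i}.ttl"
        nt = tmp_path / f"kg{i}.nt"
        export_turtle(kg, ttl)
        export_ntriples(kg, nt)
        paths.append((ttl.read_bytes(), nt.read_bytes()))
    assert paths[0] == paths[1]


def test_label_with_quotes_escaped_roundtrip(tmp_path):
    from ocmrkit.kg_builder import KnowledgeGraph

    kg = KnowledgeGraph()
    t = TermId("CHEBI", "1")
    kg.add(Triple(t, IS_A, TermId("CHEBI", "2"), "is_a"))
    kg.set_label(t, 'said "hi"\nback')
    out = tmp_path / "esc.nt"
    export_ntriples(kg, out)
    assert parse_ntriples(out).labels[t] == 'said "hi"\nback'
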