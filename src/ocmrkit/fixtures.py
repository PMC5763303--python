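"""Accessors for the small reference fixtures shipped with the package."""

from __future__ import annotations

from importlib import resources

from .curation_ingest import CurationTable, parse_curation_table
from .kg_builder import KnowledgeGraph, build_kg
from .ontology_model import OntologyGraph, TermId, load_obo

__all__ = [
    "ANTI_INFLAMMATORY",
    "ANTINEOPLASTIC",
    "fixture_path",
    "table1_table",
    "table1_kg",
    "toy_taxonomy",
    "chebi_role_slice",
    "toy_lipid",
    "toy_oae",
]

ANTI_INFLAMMATORY = TermId("CHEBI", "67079")
ANTINEOPLASTIC = TermId("CHEBI", "35610")


def fixture_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files("ocmrkit.data").joinpath(name)


def table1_table() -> CurationTable:
    """The packaged per-role ingredient table (42 entries, 19 drugs)."""
    with resources.as_file(fixture_path("table1_roles.tsv")) as p:
        return parse_curation_table(p)


def _load(name: str) -> OntologyGraph:
    with resources.as_file(fixture_path(name)) as p:
        return load_obo(p)


def toy_taxonomy() -> OntologyGraph:
    return _load("toy_taxonomy.obo")


def chebi_role_slice() -> OntologyGraph:
    return _load("chebi_role_slice.obo")


def toy_lipid() -> OntologyGraph:
    return _load("toy_lipid.obo")


def toy_oae() -> OntologyGraph:
    return _load("toy_oae.obo")


def table1_kg() -> KnowledgeGraph:
    """Knowledge graph built from the per-role ingredient table plus the
    role-hierarchy slice."""
    return build_kg(table1_table(), {"chebi": chebi_role_slice()})
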