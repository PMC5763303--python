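"""Knowledge-graph construction from a curation table plus ontology slices.

Drug classes are minted deterministically in a local namespace, linked to
their ingredients, adverse events and sources by existential-restriction
axioms, and merged with the imported ``is_a`` / ``has_role`` hierarchy
triples.  Two serializations are provided: Turtle with the standard
``subClassOf``/``owl:Restriction``/``someValuesFrom`` pattern, and a
materialized N-Triples form where every existential axiom is flattened to a
direct predicate edge (the query-ready form).  Both are byte-deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from .curation_ingest import CurationRow, CurationTable, normalize_label
from .ontology_model import OBO_PURL_BASE, OntologyGraph, TermId

__all__ = [
    "IS_A",
    "ROLE_TERMS",
    "RelationConfig",
    "Triple",
    "KnowledgeGraph",
    "AxiomTemplate",
    "TemplateResult",
    "KGBuildError",
    "mint_drug_terms",
    "mint_drug_term",
    "apply_template",
    "build_kg",
    "export_turtle",
    "export_ntriples",
    "parse_ntriples",
]

RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"

#: pseudo relation id used for hierarchy triples; serialized as rdfs:subClassOf
IS_A = TermId("rdfs", "subClassOf")

#: curator role name -> ChEBI role term
ROLE_TERMS: Mapping[str, tuple[TermId, str]] = {
    "anti-inflammatory": (TermId("CHEBI", "67079"), "anti-inflammatory agent"),
    "antineoplastic": (TermId("CHEBI", "35610"), "antineoplastic agent"),
}


class KGBuildError(ValueError):
    pass


@dataclass(frozen=True)
class RelationConfig:
    """Relation CURIEs + labels used when instantiating the design pattern.

    The drug->organism and drug->anatomy relations are configurable because
    no single standard relation is mandated for them; the defaults below are
    RO's 'produced by' and 'derives from'.
    """

    has_part: TermId = TermId("BFO", "0000051")
    participates_in: TermId = TermId("RO", "0000056")
    has_role: TermId = TermId("RO", "0000087")
    produced_by: TermId = TermId("RO", "0003001")
    derives_from: TermId = TermId("RO", "0001000")
    labels: Mapping[str, str] = field(
        default_factory=lambda: {
            "has_part": "has part",
            "participates_in": "participates in",
            "has_role": "has role",
            "produced_by": "produced by",
            "derives_from": "derives from",
        }
    )

    def __post_init__(self) -> None:
        curies = [self.has_part, self.participates_in, self.has_role,
                  self.produced_by, self.derives_from]
        if len(set(curies)) != len(curies):
            raise KGBuildError("duplicate relation CURIEs in RelationConfig")
        for name in self.names():
            if not self.labels.get(name):
                raise KGBuildError(f"relation {name!r} lacks a label")

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("has_part", "participates_in", "has_role", "produced_by",
                "derives_from")

    def relation(self, name: str) -> TermId:
        if name not in self.names():
            raise KGBuildError(f"unknown relation name {name!r}")
        return getattr(self, name)

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "RelationConfig":
        rc = cls()
        overrides = {}
        labels = dict(rc.labels)
        for name, value in data.items():
            if name not in cls.names():
                raise KGBuildError(f"unknown relation name {name!r}")
            if isinstance(value, Mapping):
                overrides[name] = TermId.parse(str(value["curie"]))
                if "label" in value:
                    labels[name] = str(value["label"])
            else:
                overrides[name] = TermId.parse(str(value))
        return replace(rc, labels=labels, **overrides)


@dataclass(frozen=True, order=True)
class Triple:
    subject: TermId
    predicate: TermId
    object: TermId
    axiom_kind: str = "existential"  # or "is_a"

    def __post_init__(self) -> None:
        if self.axiom_kind not in ("is_a", "existential"):
            raise ValueError(f"bad axiom_kind {self.axiom_kind!r}")


class KnowledgeGraph:
    """A deduplicated set of triples with term labels and drug provenance."""

    def __init__(self) -> None:
        self.triples: set[Triple] = set()
        self.labels: dict[TermId, str] = {}
        self.provenance: dict[TermId, list[CurationRow]] = {}
        self._super: dict[TermId, set[TermId]] = {}
        self._sub: dict[TermId, set[TermId]] = {}

    def add(self, triple: Triple) -> None:
        self.triples.add(triple)
        if triple.axiom_kind == "is_a":
            self._super.setdefault(triple.subject, set()).add(triple.object)
            self._sub.setdefault(triple.object, set()).add(triple.subject)

    def set_label(self, t: TermId, label: str) -> None:
        if label:
            self.labels[t] = label

    def terms(self) -> set[TermId]:
        out: set[TermId] = set()
        for tr in self.triples:
            out.add(tr.subject)
            out.add(tr.object)
        return out

    def matching(
        self,
        subject: TermId | None = None,
        predicate: TermId | None = None,
        object: TermId | None = None,
    ) -> Iterator[Triple]:
        for tr in self.triples:
            if subject is not None and tr.subject != subject:
                continue
            if predicate is not None and tr.predicate != predicate:
                continue
            if object is not None and tr.object != object:
                continue
            yield tr

    # -- hierarchy closure over is_a triples --------------------------------
    def superclasses(self, t: TermId, reflexive: bool = True) -> set[TermId]:
        seen: set[TermId] = set()
        stack = list(self._super.get(t, ()))
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self._super.get(cur, ()))
        if reflexive:
            seen.add(t)
        return seen

    def subclasses(self, t: TermId, reflexive: bool = True) -> set[TermId]:
        seen: set[TermId] = set()
        stack = list(self._sub.get(t, ()))
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self._sub.get(cur, ()))
        if reflexive:
            seen.add(t)
        return seen


# -- drug term minting -----------------------------------------------------

_NAMESPACE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*$")


def mint_drug_terms(
    labels: Iterable[str], namespace: str = "OCMR", start: int = 1
) -> dict[str, TermId]:
    """Assign zero-padded sequential ids in sorted normalized-label order.

    Deterministic: the same label set always yields the same id map.  Keys of
    the returned map are normalized labels.
    """
    if not _NAMESPACE_RE.match(namespace):
        raise KGBuildError(f"malformed namespace {namespace!r}")
    normalized = sorted({normalize_label(l) for l in labels if l.strip()})
    return {
        label: TermId(namespace, f"{i:07d}")
        for i, label in enumerate(normalized, start=start)
    }


def mint_drug_term(
    drug_label: str, namespace: str, all_labels: Iterable[str]
) -> TermId:
    if not drug_label.strip():
        raise KGBuildError("drug label must be nonempty")
    return mint_drug_terms(all_labels, namespace)[normalize_label(drug_label)]


# -- template application --------------------------------------------------

_FIELD_ATTRS = {
    "chemical_id": "chemical_id",
    "ae_id": "ae_id",
    "organism_id": "organism",
    "anatomy_id": "anatomy",
}


@dataclass(frozen=True)
class AxiomTemplate:
    """Pattern like ``"{drug} has_part {chemical_id}"``: subject placeholder,
    relation name from :class:`RelationConfig`, object placeholder."""

    pattern: str

    def parse(self) -> tuple[str, str, str]:
        parts = self.pattern.split()
        if (
            len(parts) != 3
            or parts[0] != "{drug}"
            or not (parts[2].startswith("{") and parts[2].endswith("}"))
        ):
            raise KGBuildError(f"malformed template {self.pattern!r}")
        obj_field = parts[2][1:-1]
        if obj_field not in _FIELD_ATTRS:
            raise KGBuildError(f"unknown template field {obj_field!r}")
        return "drug", parts[1], obj_field


@dataclass
class TemplateResult:
    triples: set[Triple]
    skipped: int


def apply_template(
    tpl: AxiomTemplate, ct: CurationTable, rc: RelationConfig | None = None
) -> TemplateResult:
    """One existential triple per row carrying the object field; rows missing
    it are skipped and counted."""
    rc = rc or RelationConfig()
    _, rel_name, obj_field = tpl.parse()
    relation = rc.relation(rel_name)
    drug_ids = mint_drug_terms(r.drug_label for r in ct.rows)
    triples: set[Triple] = set()
    skipped = 0
    for row in ct.rows:
        value = getattr(row, _FIELD_ATTRS[obj_field])
        if value is None:
            skipped += 1
            continue
        subject = drug_ids[normalize_label(row.drug_label)]
        triples.add(Triple(subject, relation, value))
    return TemplateResult(triples=triples, skipped=skipped)


# -- full build ------------------------------------------------------------

def build_kg(
    ct: CurationTable,
    ontologies: Mapping[str, OntologyGraph] | None = None,
    rc: RelationConfig | None = None,
    role_terms: Mapping[str, tuple[TermId, str]] = ROLE_TERMS,
    namespace: str = "OCMR",
) -> KnowledgeGraph:
    """Materialize the design pattern over a validated curation table.

    Produces (i) minted drug classes under their category parents, (ii) one
    existential triple per chemical / AE / source fact, (iii) all imported
    ``is_a`` and cross-link triples from the supplied ontology slices, and
    (iv) curator role assertions as ``has_role`` triples.
    """
    ontologies = ontologies or {}
    rc = rc or RelationConfig()
    kg = KnowledgeGraph()

    # reject distinct raw labels that collide after normalization
    raw_by_norm: dict[str, set[str]] = {}
    for r in ct.rows:
        raw_by_norm.setdefault(normalize_label(r.drug_label), set()).add(
            r.drug_label.strip()
        )
    for norm, raws in sorted(raw_by_norm.items()):
        if len(raws) > 1:
            raise KGBuildError(
                f"duplicate drug label after normalization: {sorted(raws)}"
            )

    drug_ids = mint_drug_terms((r.drug_label for r in ct.rows), namespace)
    categories = sorted(
        {normalize_label(r.drug_category) for r in ct.rows if r.drug_category.strip()}
    )
    category_ids = {
        c: TermId(namespace, f"{i:07d}")
        for i, c in enumerate(categories, start=len(drug_ids) + 1)
    }

    for norm, raws in sorted(raw_by_norm.items()):
        kg.set_label(drug_ids[norm], next(iter(raws)))
    for r in ct.rows:
        if r.drug_category.strip():
            kg.set_label(category_ids[normalize_label(r.drug_category)],
                         r.drug_category.strip())

    # (i) drug classification
    seen_cat: set[tuple[str, str]] = set()
    for r in ct.rows:
        if not r.drug_category.strip():
            continue
        key = (normalize_label(r.drug_label), normalize_label(r.drug_category))
        if key in seen_cat:
            continue
        seen_cat.add(key)
        kg.add(Triple(drug_ids[key[0]], IS_A, category_ids[key[1]], "is_a"))

    # (ii) existential facts + (iv) curator roles
    for row in ct.rows:
        drug = drug_ids[normalize_label(row.drug_label)]
        kg.provenance.setdefault(drug, []).append(row)
        if row.fact_type == "chemical" and row.chemical_id is not None:
            kg.add(Triple(drug, rc.has_part, row.chemical_id))
            if row.chemical_label:
                kg.set_label(row.chemical_id, row.chemical_label)
            for role_name in sorted(row.roles):
                if role_name not in role_terms:
                    raise KGBuildError(f"no role term configured for {role_name!r}")
                role_id, role_label = role_terms[role_name]
                kg.add(Triple(row.chemical_id, rc.has_role, role_id))
                kg.set_label(role_id, role_label)
        elif row.fact_type == "ae" and row.ae_id is not None:
            kg.add(Triple(drug, rc.participates_in, row.ae_id))
            if row.ae_label:
                kg.set_label(row.ae_id, row.ae_label)
        elif row.fact_type == "source":
            if row.organism is not None:
                kg.add(Triple(drug, rc.produced_by, row.organism))
            if row.anatomy is not None:
                kg.add(Triple(drug, rc.derives_from, row.anatomy))

    # (iii) imported hierarchies
    for _name in sorted(ontologies):
        g = ontologies[_name]
        for child, parent in sorted(g.is_a):
            kg.add(Triple(child, IS_A, parent, "is_a"))
        for s, rel, o in sorted(g.cross_links):
            kg.add(Triple(s, rel, o))
        for t in g.terms.values():
            kg.set_label(t.id, t.label)
    for name in rc.names():
        kg.set_label(rc.relation(name), rc.labels[name])
    return kg


# -- serialization ---------------------------------------------------------

def _iri(t: TermId) -> str:
    if t.prefix == "rdfs":
        return RDFS_NS + t.local
    return OBO_PURL_BASE + t.iri_form


def _term_from_iri(iri: str) -> TermId:
    if iri.startswith(RDFS_NS):
        return TermId("rdfs", iri[len(RDFS_NS):])
    if iri.startswith(OBO_PURL_BASE):
        return TermId.parse(iri[len(OBO_PURL_BASE):])
    raise ValueError(f"unrecognized IRI {iri!r}")


def _escape_literal(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def export_turtle(kg: KnowledgeGraph, path) -> None:
    """OWL-flavored Turtle: named classes, rdfs:label annotations, is_a as
    rdfs:subClassOf, existential triples as someValuesFrom restrictions.
    Subjects sorted by IRI; byte-deterministic."""
    by_subject: dict[TermId, list[Triple]] = {}
    for tr in kg.triples:
        by_subject.setdefault(tr.subject, []).append(tr)
    subjects = sorted(set(by_subject) | set(kg.labels) | kg.terms(),
                      key=_iri)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@prefix obo: <http://purl.obolibrary.org/obo/> .\n")
        fh.write("@prefix owl: <http://www.w3.org/2002/07/owl#> .\n")
        fh.write("@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n")
        for s in subjects:
            if s.prefix == "rdfs":
                continue
            lines = [f"<{_iri(s)}> a owl:Class"]
            if s in kg.labels:
                lines.append(f'    rdfs:label "{_escape_literal(kg.labels[s])}"')
            for tr in sorted(by_subject.get(s, [])):
                if tr.axiom_kind == "is_a":
                    lines.append(f"    rdfs:subClassOf <{_iri(tr.object)}>")
                else:
                    lines.append(
                        "    rdfs:subClassOf [ a owl:Restriction ; "
                        f"owl:onProperty <{_iri(tr.predicate)}> ; "
                        f"owl:someValuesFrom <{_iri(tr.object)}> ]"
                    )
            fh.write("\n" + " ;\n".join(lines) + " .\n")


def export_ntriples(kg: KnowledgeGraph, path) -> None:
    """Materialized N-Triples: every triple flattened to a direct predicate
    edge (is_a as rdfs:subClassOf); labels emitted as rdfs:label literals.
    Lines sorted; byte-deterministic."""
    lines = set()
    for tr in kg.triples:
        pred = RDFS_NS + "subClassOf" if tr.axiom_kind == "is_a" else _iri(tr.predicate)
        lines.add(f"<{_iri(tr.subject)}> <{pred}> <{_iri(tr.object)}> .")
    for t, label in kg.labels.items():
        lines.add(
            f'<{_iri(t)}> <{RDFS_NS}label> "{_escape_literal(label)}" .'
        )
    with open(path, "w", encoding="utf-8") as fh:
        for line in sorted(lines):
            fh.write(line + "\n")


_NT_RE = re.compile(
    r'^<(?P<s>[^>]+)>\s+<(?P<p>[^>]+)>\s+(?:<(?P<o>[^>]+)>|"(?P<lit>(?:[^"\\]|\\.)*)")\s*\.\s*$'
)


def parse_ntriples(path) -> KnowledgeGraph:
    """Read a materialized N-Triples file back into a KnowledgeGraph."""
    kg = KnowledgeGraph()
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = _NT_RE.match(line)
            if m is None:
                raise ValueError(f"line {line_no}: unparseable N-Triples line")
            s = _term_from_iri(m.group("s"))
            p_iri = m.group("p")
            if m.group("lit") is not None:
                if p_iri == RDFS_NS + "label":
                    lit = m.group("lit")
                    lit = (
                        lit.replace("\\n", "\n").replace('\\"', '"')
                        .replace("\\\\", "\\")
                    )
                    kg.set_label(s, lit)
                continue
            o = _term_from_iri(m.group("o"))
            if p_iri == RDFS_NS + "subClassOf":
                kg.add(Triple(s, IS_A, o, "is_a"))
            else:
                kg.add(Triple(s, _term_from_iri(p_iri), o))
    return kg
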