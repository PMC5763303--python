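"""In-memory DAG model of an ontology slice, with OBO-flavored reading and writing.

The model is deliberately small: terms with labels/synonyms, ``is_a`` edges
forming a rooted multi-parent DAG, and non-hierarchical cross links (typically
``has_role``).  Closures (:func:`ancestors`, :func:`descendants`) are computed
over ``is_a`` only; cross links never participate in the cycle check.

Identifier dialects: both colon CURIEs (``CHEBI:9747``) and underscore forms
(``CHEBI_9747``), as well as OBO PURL IRIs, normalize to one canonical colon
CURIE.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "TermId",
    "Term",
    "OntologyGraph",
    "OboParseError",
    "OntologyError",
    "CycleError",
    "DanglingEdgeError",
    "UnknownTermError",
    "load_obo",
    "parse_obo",
    "write_obo",
    "ancestors",
    "descendants",
    "is_ancestor",
]

OBO_PURL_BASE = "http://purl.obolibrary.org/obo/"

_IRI_RE = re.compile(r"^https?://purl\.obolibrary\.org/obo/(.+)$")


class OntologyError(ValueError):
    """Base class for ontology model errors."""


class OboParseError(OntologyError):
    """Raised when an OBO-flavored file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class CycleError(OntologyError):
    """Raised when is_a edges contain a directed cycle."""

    def __init__(self, cycle: list["TermId"]):
        self.cycle = cycle
        super().__init__(
            "is_a cycle detected: " + " -> ".join(t.curie for t in cycle)
        )


class DanglingEdgeError(OntologyError):
    """Raised when an edge references an undeclared term."""

    def __init__(self, missing: "TermId"):
        self.missing = missing
        super().__init__(f"edge references undeclared term {missing.curie}")


class UnknownTermError(OntologyError, KeyError):
    def __init__(self, term: "TermId"):
        self.term = term
        ValueError.__init__(self, f"unknown term {term.curie}")


@dataclass(frozen=True, order=True)
class TermId:
    """A compact ontology identifier, canonically ``PREFIX:LOCAL``."""

    prefix: str
    local: str

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValueError("TermId prefix must be non-empty")
        if not self.local:
            raise ValueError("TermId local part must be non-empty")

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local}"

    @property
    def iri_form(self) -> str:
        """Underscore identifier as used in OBO PURLs (``CHEBI_9747``)."""
        return f"{self.prefix}_{self.local}"

    @property
    def iri(self) -> str:
        return OBO_PURL_BASE + self.iri_form

    @classmethod
    def parse(cls, s: str) -> "TermId":
        """Parse any accepted dialect: ``CHEBI:9747``, ``CHEBI_9747`` or a PURL IRI.

        For the underscore dialect the split is on the *last* underscore, so
        prefixes themselves must not end in ``_``; this matches OBO Foundry
        identifier style.
        """
        s = s.strip()
        m = _IRI_RE.match(s)
        if m:
            s = m.group(1)
        if ":" in s:
            prefix, _, local = s.partition(":")
        elif "_" in s:
            prefix, _, local = s.rpartition("_")
        else:
            raise ValueError(f"cannot parse term identifier {s!r}")
        prefix, local = prefix.strip(), local.strip()
        if not prefix or not local:
            raise ValueError(f"cannot parse term identifier {s!r}")
        return cls(prefix, local)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


@dataclass
class Term:
    id: TermId
    label: str = ""
    synonyms: list[str] = field(default_factory=list)
    obsolete: bool = False


class OntologyGraph:
    """Rooted multi-parent ``is_a`` DAG with labels and cross links.

    ``is_a`` edges are (child, parent) pairs.  Cross links are
    (subject, relation, object) triples, e.g. ``has_role`` assertions.
    Obsolete terms are kept for provenance but excluded from closures.
    """

    def __init__(self) -> None:
        self.terms: dict[TermId, Term] = {}
        self.is_a: set[tuple[TermId, TermId]] = set()
        self.cross_links: set[tuple[TermId, TermId, TermId]] = set()
        self._parents: dict[TermId, set[TermId]] = {}
        self._children: dict[TermId, set[TermId]] = {}

    # -- construction ------------------------------------------------------
    def add_term(self, term: Term) -> None:
        self.terms[term.id] = term
        self._parents.setdefault(term.id, set())
        self._children.setdefault(term.id, set())

    def add_is_a(self, child: TermId, parent: TermId) -> None:
        for t in (child, parent):
            if t not in self.terms:
                raise DanglingEdgeError(t)
        self.is_a.add((child, parent))
        self._parents[child].add(parent)
        self._children[parent].add(child)

    def add_cross_link(self, subject: TermId, relation: TermId, obj: TermId) -> None:
        self.cross_links.add((subject, relation, obj))

    # -- basic accessors ---------------------------------------------------
    def __contains__(self, t: TermId) -> bool:
        return t in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[TermId]:
        return iter(sorted(self.terms))

    def label(self, t: TermId) -> str:
        return self.terms[t].label if t in self.terms else ""

    def parents(self, t: TermId) -> set[TermId]:
        if t not in self.terms:
            raise UnknownTermError(t)
        return {p for p in self._parents[t] if not self.terms[p].obsolete}

    def children(self, t: TermId) -> set[TermId]:
        if t not in self.terms:
            raise UnknownTermError(t)
        return {c for c in self._children[t] if not self.terms[c].obsolete}

    @property
    def roots(self) -> set[TermId]:
        return {
            t
            for t in self.terms
            if not self.terms[t].obsolete and not self.parents(t)
        }

    def active_terms(self) -> set[TermId]:
        return {t for t, term in self.terms.items() if not term.obsolete}

    def find_by_label(self, label: str) -> TermId | None:
        """Case-insensitive, whitespace-collapsed label lookup."""
        key = _norm(label)
        for t, term in sorted(self.terms.items()):
            if _norm(term.label) == key:
                return t
        return None

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check the DAG invariant over non-obsolete is_a edges."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.active_terms())
        for c, p in self.is_a:
            if not (self.terms[c].obsolete or self.terms[p].obsolete):
                dg.add_edge(c, p)
        try:
            cycle_edges = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([e[0] for e in cycle_edges])


def _norm(s: str) -> str:
    return " ".join(s.split()).casefold()


# -- closures --------------------------------------------------------------

def ancestors(g: OntologyGraph, t: TermId) -> set[TermId]:
    """Reflexive-free transitive closure of ``is_a`` parents of ``t``."""
    if t not in g.terms:
        raise UnknownTermError(t)
    seen: set[TermId] = set()
    stack = list(g.parents(t))
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(g.parents(cur))
    return seen


def descendants(g: OntologyGraph, t: TermId) -> set[TermId]:
    """All terms that reach ``t`` via is_a; dual of :func:`ancestors`."""
    if t not in g.terms:
        raise UnknownTermError(t)
    seen: set[TermId] = set()
    stack = list(g.children(t))
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(g.children(cur))
    return seen


def is_ancestor(g: OntologyGraph, a: TermId, b: TermId) -> bool:
    """True iff ``a`` is a proper is_a ancestor of ``b`` (irreflexive)."""
    if a not in g.terms:
        raise UnknownTermError(a)
    return a in ancestors(g, b)


# -- OBO-flavored I/O ------------------------------------------------------
#
# Supported stanza subset: [Term] with id, name, synonym, is_a,
# relationship, is_obsolete.  Header lines before the first stanza are
# ignored except format-version.

def parse_obo(lines: Iterable[str]) -> OntologyGraph:
    g = OntologyGraph()
    pending_is_a: list[tuple[TermId, TermId, int]] = []
    pending_links: list[tuple[TermId, str, TermId, int]] = []
    current: Term | None = None
    in_term = False

    def flush() -> None:
        nonlocal current
        if current is not None:
            g.add_term(current)
        current = None

    for line_no, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if not in_term and line not in ("[Typedef]", "[Instance]"):
                raise OboParseError(f"unknown stanza {line}", line_no)
            continue
        if ":" not in line:
            raise OboParseError(f"expected 'tag: value', got {line!r}", line_no)
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if not in_term:
            continue
        if tag == "id":
            flush()
            try:
                current = Term(TermId.parse(value))
            except ValueError as exc:
                raise OboParseError(str(exc), line_no) from exc
        elif current is None:
            raise OboParseError(f"tag {tag!r} before id", line_no)
        elif tag == "name":
            current.label = value
        elif tag == "synonym":
            m = re.match(r'"(.*)"', value)
            current.synonyms.append(m.group(1) if m else value)
        elif tag == "is_a":
            try:
                pending_is_a.append((current.id, TermId.parse(value), line_no))
            except ValueError as exc:
                raise OboParseError(str(exc), line_no) from exc
        elif tag == "relationship":
            parts = value.split(None, 1)
            if len(parts) != 2:
                raise OboParseError(f"malformed relationship {value!r}", line_no)
            rel, target = parts
            try:
                pending_links.append((current.id, rel, TermId.parse(target), line_no))
            except ValueError as exc:
                raise OboParseError(str(exc), line_no) from exc
        elif tag == "is_obsolete":
            current.obsolete = value.lower() == "true"
        # other tags (def, xref, ...) are silently ignored
    flush()

    for child, parent, line_no in pending_is_a:
        try:
            g.add_is_a(child, parent)
        except DanglingEdgeError as exc:
            raise OboParseError(str(exc), line_no) from exc
    for subj, rel, target, line_no in pending_links:
        if target not in g.terms:
            raise OboParseError(
                f"relationship target undeclared: {target.curie}", line_no
            )
        g.add_cross_link(subj, RELATION_IDS.get(rel, TermId("rel", rel)), target)
    g.validate()
    return g


#: OBO shorthand relation names -> canonical relation term ids.
RELATION_IDS: Mapping[str, TermId] = {
    "has_role": TermId("RO", "0000087"),
    "has_part": TermId("BFO", "0000051"),
    "participates_in": TermId("RO", "0000056"),
}

_RELATION_NAMES = {v: k for k, v in RELATION_IDS.items()}


def load_obo(path) -> OntologyGraph:
    """Load an OBO-flavored flat file into an :class:`OntologyGraph`."""
    with open(path, encoding="utf-8") as fh:
        return parse_obo(fh)


def write_obo(g: OntologyGraph, path) -> None:
    """Serialize the graph in the same OBO dialect, terms and edges sorted
    by CURIE so output is byte-stable."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        links_by_subject: dict[TermId, list[tuple[TermId, TermId]]] = {}
        for s, r, o in self_sorted(g.cross_links):
            links_by_subject.setdefault(s, []).append((r, o))
        for tid in sorted(g.terms):
            term = g.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {tid.curie}\n")
            if term.label:
                fh.write(f"name: {term.label}\n")
            for syn in term.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(g._parents[tid]):
                fh.write(f"is_a: {parent.curie}\n")
            for rel, obj in links_by_subject.get(tid, []):
                name = _RELATION_NAMES.get(rel, rel.curie)
                fh.write(f"relationship: {name} {obj.curie}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")


def self_sorted(links: Iterable[tuple[TermId, TermId, TermId]]):
    return sorted(links)
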