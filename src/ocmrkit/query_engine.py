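"""Conjunctive triple-pattern matching over a materialized knowledge graph.

This is the basic-graph-pattern fragment only: a list of patterns joined on
shared variables.  A pattern's predicate may be flagged transitive, in which
case it matches through the reflexive-transitive closure of that predicate's
edges (the usual way to walk ``rdfs:subClassOf``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .kg_builder import IS_A, KnowledgeGraph
from .ontology_model import TermId

__all__ = ["Var", "TriplePattern", "Bindings", "match_pattern", "select"]


@dataclass(frozen=True, order=True)
class Var:
    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be nonempty")


Atom = Union[Var, TermId]


@dataclass(frozen=True)
class TriplePattern:
    subject: Atom
    predicate: Atom
    object: Atom
    transitive: bool = False

    def __post_init__(self) -> None:
        if self.transitive and isinstance(self.predicate, Var):
            raise ValueError("transitive flag requires a constant predicate")

    @property
    def variables(self) -> set[str]:
        return {a.name for a in (self.subject, self.predicate, self.object)
                if isinstance(a, Var)}


@dataclass
class Bindings:
    """Deduplicated solution maps, sorted by their bound CURIEs."""

    variables: tuple[str, ...]
    solutions: list[dict[str, TermId]]

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def column(self, var: str) -> list[TermId]:
        return [sol[var] for sol in self.solutions]


def _closure_pairs(
    kg: KnowledgeGraph, predicate: TermId
) -> dict[TermId, set[TermId]]:
    """Reflexive-transitive closure of one predicate's edge relation."""
    adj: dict[TermId, set[TermId]] = {}
    for tr in kg.triples:
        eff = IS_A if tr.axiom_kind == "is_a" else tr.predicate
        if eff == predicate:
            adj.setdefault(tr.subject, set()).add(tr.object)
    closure: dict[TermId, set[TermId]] = {}

    def reach(n: TermId) -> set[TermId]:
        if n in closure:
            return closure[n]
        closure[n] = {n}  # reflexive; also guards cyclic input
        out = {n}
        for nxt in adj.get(n, ()):
            out |= reach(nxt)
        closure[n] = out
        return out

    for node in set(adj) | {o for outs in adj.values() for o in outs} | kg.terms():
        reach(node)
    return closure


def _pattern_matches(
    kg: KnowledgeGraph, pattern: TriplePattern
) -> Iterable[tuple[TermId, TermId, TermId]]:
    if pattern.transitive:
        assert isinstance(pattern.predicate, TermId)
        closure = _closure_pairs(kg, pattern.predicate)
        for s, objs in closure.items():
            for o in objs:
                yield (s, pattern.predicate, o)
    else:
        for tr in kg.triples:
            eff = IS_A if tr.axiom_kind == "is_a" else tr.predicate
            yield (tr.subject, eff, tr.object)


def _unify(
    binding: dict[str, TermId],
    pattern: TriplePattern,
    triple: tuple[TermId, TermId, TermId],
) -> dict[str, TermId] | None:
    new = dict(binding)
    for atom, value in zip((pattern.subject, pattern.predicate, pattern.object),
                           triple):
        if isinstance(atom, Var):
            bound = new.get(atom.name)
            if bound is None:
                new[atom.name] = value
            elif bound != value:
                return None
        elif atom != value:
            return None
    return new


def match_pattern(
    kg: KnowledgeGraph, patterns: Sequence[TriplePattern]
) -> Bindings:
    """Join semantics: a solution satisfies every pattern simultaneously.

    Equivalent to the brute-force filter-and-join over all triples; results
    are deduplicated and sorted by bound CURIEs.  An all-constant pattern set
    acts as an ASK: one empty solution if satisfied, none otherwise.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("at least one pattern is required")
    solutions: list[dict[str, TermId]] = [{}]
    for pattern in patterns:
        candidates = list(_pattern_matches(kg, pattern))
        next_solutions: list[dict[str, TermId]] = []
        for binding in solutions:
            for triple in candidates:
                unified = _unify(binding, pattern, triple)
                if unified is not None:
                    next_solutions.append(unified)
        solutions = next_solutions
        if not solutions:
            break
    variables = tuple(sorted(set().union(*(p.variables for p in patterns))))
    deduped = {
        tuple(sol[v] for v in variables): sol for sol in solutions
    }
    ordered = [deduped[k] for k in sorted(deduped, key=lambda key: tuple(t.curie for t in key))]
    return Bindings(variables=variables, solutions=ordered)


def select(
    kg: KnowledgeGraph, patterns: Sequence[TriplePattern], variables: Sequence[str]
) -> Bindings:
    """match_pattern followed by projection onto ``variables`` (deduplicated)."""
    full = match_pattern(kg, patterns)
    for v in variables:
        if v not in full.variables:
            raise ValueError(f"unknown variable {v!r}")
    seen: dict[tuple[TermId, ...], dict[str, TermId]] = {}
    for sol in full.solutions:
        key = tuple(sol[v] for v in variables)
        seen.setdefault(key, {v: sol[v] for v in variables})
    ordered = [seen[k] for k in sorted(seen, key=lambda key: tuple(t.curie for t in key))]
    return Bindings(variables=tuple(variables), solutions=ordered)
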