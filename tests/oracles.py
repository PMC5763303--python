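"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the traversal code under test: path enumeration for
closures, networkx transitive closure for predicate reachability, and a
nested-loop join for query evaluation.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx

from ocmrkit.kg_builder import IS_A, KnowledgeGraph, Triple
from ocmrkit.ontology_model import OntologyGraph, Term, TermId
from ocmrkit.query_engine import TriplePattern, Var


def make_tid(i: int, prefix: str = "T") -> TermId:
    return TermId(prefix, f"{i:04d}")


def random_dag(
    rng: random.Random, n_nodes: int, max_parents: int = 3
) -> OntologyGraph:
    """Layered random DAG: node i may only have parents among nodes < i."""
    g = OntologyGraph()
    ids = [make_tid(i) for i in range(n_nodes)]
    for i, tid in enumerate(ids):
        g.add_term(Term(tid, label=f"t{i}"))
        if i == 0:
            continue
        n_par = rng.randint(0 if i > 1 else 1, min(max_parents, i))
        if i > 1 and n_par == 0 and rng.random() < 0.8:
            n_par = 1  # keep the graph mostly connected
        for parent in rng.sample(ids[:i], n_par):
            g.add_is_a(tid, parent)
    return g


def random_tree(rng: random.Random, n_nodes: int) -> OntologyGraph:
    g = OntologyGraph()
    ids = [make_tid(i) for i in range(n_nodes)]
    for i, tid in enumerate(ids):
        g.add_term(Term(tid, label=f"t{i}"))
        if i > 0:
            g.add_is_a(tid, ids[rng.randrange(i)])
    return g


def ancestors_by_path_enumeration(g: OntologyGraph, t: TermId) -> set[TermId]:
    """All terms on any child-to-parent path from t, excluding t."""
    found: set[TermId] = set()

    def walk(path: list[TermId]) -> None:
        for parent in g.parents(path[-1]):
            if parent in path:  # would be a cycle; DAG makes this impossible
                continue
            found.add(parent)
            walk(path + [parent])

    walk([t])
    return found


def steiner_nodes_on_tree(g: OntologyGraph, seeds: set[TermId]) -> set[TermId]:
    """Seeds plus internal nodes with >= 2 seed-bearing child subtrees."""

    def subtree_has_seed(n: TermId) -> bool:
        stack = [n]
        while stack:
            cur = stack.pop()
            if cur in seeds:
                return True
            stack.extend(g.children(cur))
        return False

    out = set(seeds)
    for node in g.terms:
        bearing = [c for c in g.children(node) if subtree_has_seed(c)]
        if len(bearing) >= 2:
            out.add(node)
    return out


def nested_loop_join(
    kg: KnowledgeGraph, patterns: list[TriplePattern]
) -> set[tuple[tuple[str, TermId], ...]]:
    """Exhaustive join: try every combination of matching triples."""
    candidate_lists = []
    for pattern in patterns:
        if pattern.transitive:
            dg = nx.DiGraph()
            dg.add_nodes_from(kg.terms())
            for tr in kg.triples:
                eff = IS_A if tr.axiom_kind == "is_a" else tr.predicate
                if eff == pattern.predicate:
                    dg.add_edge(tr.subject, tr.object)
            tc = nx.transitive_closure(dg, reflexive=True)
            candidate_lists.append(
                [(s, pattern.predicate, o) for s, o in tc.edges()]
            )
        else:
            candidate_lists.append(
                [
                    (tr.subject,
                     IS_A if tr.axiom_kind == "is_a" else tr.predicate,
                     tr.object)
                    for tr in kg.triples
                ]
            )
    solutions: set[tuple[tuple[str, TermId], ...]] = set()
    for combo in itertools.product(*candidate_lists):
        binding: dict[str, TermId] = {}
        ok = True
        for pattern, triple in zip(patterns, combo):
            for atom, value in zip(
                (pattern.subject, pattern.predicate, pattern.object), triple
            ):
                if isinstance(atom, Var):
                    if binding.setdefault(atom.name, value) != value:
                        ok = False
                        break
                elif atom != value:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            solutions.add(tuple(sorted(binding.items())))
    return solutions


def random_kg(rng: random.Random, n_terms: int, n_triples: int) -> KnowledgeGraph:
    """Random mixed KG: a layered is_a backbone plus random direct edges."""
    kg = KnowledgeGraph()
    ids = [make_tid(i, "K") for i in range(n_terms)]
    preds = [TermId("P", f"{j:03d}") for j in range(3)]
    for i in range(1, n_terms):
        if rng.random() < 0.6:
            kg.add(Triple(ids[i], IS_A, ids[rng.randrange(i)], "is_a"))
    while len(kg.triples) < n_triples:
        s, o = rng.choice(ids), rng.choice(ids)
        kg.add(Triple(s, rng.choice(preds), o))
    return kg
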