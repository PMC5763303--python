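"""Minimal sub-hierarchy extraction with computed intermediate ancestors.

Given a set of seed terms, the extractor keeps the seeds plus — depending on
the mode — either every ancestor, no ancestors, or only the *computed
intermediates*: branch points obtained as the fixpoint of pairwise minimal
common ancestors.  Edges in the extracted graph connect each kept term to its
nearest kept ancestors, preserving seed-to-seed reachability exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from .ontology_model import (
    OntologyGraph,
    Term,
    TermId,
    UnknownTermError,
    ancestors,
)

__all__ = [
    "ExtractionMode",
    "ExtractionOptions",
    "SubsetResult",
    "minimal_common_ancestors",
    "lca_closure",
    "extract_subset",
]


class ExtractionMode(str, Enum):
    computed_intermediates = "computed_intermediates"
    all_intermediates = "all_intermediates"
    no_intermediates = "no_intermediates"


@dataclass(frozen=True)
class ExtractionOptions:
    mode: ExtractionMode = ExtractionMode.computed_intermediates
    include_roots: bool = False
    carry_cross_links: bool = False


@dataclass
class SubsetResult:
    graph: OntologyGraph
    seed_terms: set[TermId]
    computed_terms: set[TermId]


def _check_known(g: OntologyGraph, ts) -> None:
    for t in ts:
        if t not in g.terms:
            raise UnknownTermError(t)


def minimal_common_ancestors(g: OntologyGraph, ts: set[TermId]) -> set[TermId]:
    """Minimal elements of the common ancestor-or-self set of ``ts``.

    May contain several terms under multiple inheritance.  Returns ``{t}``
    for a singleton; returns the empty set when the terms share no ancestor
    (disjoint roots in a forest).
    """
    ts = set(ts)
    if not ts:
        raise ValueError("need at least one term")
    _check_known(g, ts)
    common: set[TermId] | None = None
    for t in ts:
        anc_or_self = ancestors(g, t) | {t}
        common = anc_or_self if common is None else common & anc_or_self
    assert common is not None
    # minimal = no other common member is a proper descendant
    return {
        a
        for a in common
        if not any(b != a and a in ancestors(g, b) for b in common)
    }


def lca_closure(g: OntologyGraph, seeds: set[TermId]) -> set[TermId]:
    """Least fixpoint of adding pairwise minimal common ancestors to ``seeds``."""
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seeds must be nonempty")
    _check_known(g, seeds)
    current = set(seeds)
    while True:
        added: set[TermId] = set()
        for a, b in combinations(sorted(current), 2):
            added |= minimal_common_ancestors(g, {a, b})
        new = current | added
        if new == current:
            return current
        current = new


def _nearest_kept_ancestors(
    g: OntologyGraph, kept: set[TermId], t: TermId
) -> set[TermId]:
    """First kept term on every upward is_a path from ``t``."""
    result: set[TermId] = set()
    seen: set[TermId] = set()
    stack = list(g.parents(t))
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        if cur in kept:
            result.add(cur)
        else:
            stack.extend(g.parents(cur))
    return result


def extract_subset(
    g: OntologyGraph, seeds: set[TermId], opts: ExtractionOptions | None = None
) -> SubsetResult:
    """Extract a minimal hierarchy for ``seeds`` per ``opts``.

    Reachability preservation: for any two seeds x, y, x is an ancestor of y
    in the result iff it is in ``g``.
    """
    opts = opts or ExtractionOptions()
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seeds must be nonempty")
    _check_known(g, seeds)

    if opts.mode is ExtractionMode.computed_intermediates:
        kept = lca_closure(g, seeds)
    elif opts.mode is ExtractionMode.all_intermediates:
        kept = set(seeds)
        for s in seeds:
            kept |= ancestors(g, s)
    else:
        kept = set(seeds)

    if opts.include_roots:
        reachable_roots = {
            a for s in seeds for a in ancestors(g, s) | {s} if not g.parents(a)
        }
        kept |= reachable_roots

    sub = OntologyGraph()
    for t in sorted(kept):
        src = g.terms[t]
        sub.add_term(Term(t, src.label, list(src.synonyms), src.obsolete))
    for t in sorted(kept):
        for parent in sorted(_nearest_kept_ancestors(g, kept, t)):
            sub.add_is_a(t, parent)
    if opts.carry_cross_links:
        for s, r, o in sorted(g.cross_links):
            if s in kept and o in kept:
                sub.add_cross_link(s, r, o)
    sub.validate()
    return SubsetResult(graph=sub, seed_terms=seeds, computed_terms=kept - seeds)
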