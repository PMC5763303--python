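import random

import pytest

from ocmrkit.ontology_model import (
    OntologyGraph,
    Term,
    TermId,
    UnknownTermError,
    ancestors,
    is_ancestor,
)
from ocmrkit.subset_extraction import (
    ExtractionMode,
    ExtractionOptions,
    extract_subset,
    lca_closure,
    minimal_common_ancestors,
)
from oracles import make_tid, random_dag, random_tree, steiner_nodes_on_tree


def diamond() -> OntologyGraph:
    # x is_a a, x is_a b; y is_a a, y is_a b
    g = OntologyGraph()
    for name in "abxy":
        g.add_term(Term(TermId("D", name)))
    for child in "xy":
        for parent in "ab":
            g.add_is_a(TermId("D", child), TermId("D", parent))
    return g


def chain(n: int) -> OntologyGraph:
    g = OntologyGraph()
    ids = [make_tid(i, "C") for i in range(n)]
    for i, t in enumerate(ids):
        g.add_term(Term(t))
        if i:
            g.add_is_a(t, ids[i - 1])
    return g


# ------------------------------------------------- minimal_common_ancestors


def test_closest_ancestor_of_three_animals(toy_taxonomy, taxa):
    got = minimal_common_ancestors(
        toy_taxonomy, {taxa["tiger"], taxa["snake"], taxa["silkworm"]}
    )
    assert got == {taxa["bilateria"]}


def test_singleton_returns_itself(toy_taxonomy, taxa):
    assert minimal_common_ancestors(toy_taxonomy, {taxa["tiger"]}) == {taxa["tiger"]}


def test_diamond_yields_both_parents():
    g = diamond()
    got = minimal_common_ancestors(g, {TermId("D", "x"), TermId("D", "y")})
    assert got == {TermId("D", "a"), TermId("D", "b")}


def test_disjoint_roots_give_empty_set():
    g = OntologyGraph()
    g.add_term(Term(TermId("F", "1")))
    g.add_term(Term(TermId("F", "2")))
    assert minimal_common_ancestors(g, {TermId("F", "1"), TermId("F", "2")}) == set()


def test_unknown_term_is_an_error(toy_taxonomy):
    with pytest.raises(UnknownTermError):
        minimal_common_ancestors(toy_taxonomy, {TermId("X", "404")})


def test_mca_matches_brute_force_on_random_dags():
    for seed in range(15):
        rng = random.Random(seed)
        g = random_dag(rng, rng.randint(3, 40))
        terms = sorted(g.terms)
        a, b = rng.sample(terms, 2)
        common = (ancestors(g, a) | {a}) & (ancestors(g, b) | {b})
        brute_minimal = {
            c for c in common
            if not any(d != c and c in ancestors(g, d) for d in common)
        }
        assert minimal_common_ancestors(g, {a, b}) == brute_minimal


# ------------------------------------------------------------- lca_closure


def test_chain_seeds_unchanged():
    g = chain(6)
    seeds = {make_tid(1, "C"), make_tid(4, "C")}
    assert lca_closure(g, seeds) == seeds


def test_toy_taxonomy_closure_adds_branch_points(toy_taxonomy, taxa):
    seeds = {taxa["tiger"], taxa["snake"], taxa["silkworm"]}
    assert lca_closure(toy_taxonomy, seeds) == seeds | {
        taxa["amniota"], taxa["bilateria"]
    }


@pytest.mark.parametrize("seed", range(20))
def test_closure_equals_steiner_nodes_on_trees(seed):
    rng = random.Random(seed)
    g = random_tree(rng, rng.randint(3, 40))
    seeds = set(rng.sample(sorted(g.terms), rng.randint(2, min(6, len(g.terms)))))
    assert lca_closure(g, seeds) == steiner_nodes_on_tree(g, seeds)


@pytest.mark.parametrize("seed", range(10))
def test_closure_idempotent(seed):
    rng = random.Random(100 + seed)
    g = random_dag(rng, rng.randint(3, 30))
    seeds = set(rng.sample(sorted(g.terms), min(4, len(g.terms))))
    once = lca_closure(g, seeds)
    assert lca_closure(g, once) == once


@pytest.mark.parametrize("seed", range(10))
def test_closure_monotone_on_trees(seed):
    rng = random.Random(200 + seed)
    g = random_tree(rng, rng.randint(4, 40))
    terms = sorted(g.terms)
    big = set(rng.sample(terms, min(6, len(terms))))
    small = set(rng.sample(sorted(big), rng.randint(1, len(big))))
    assert lca_closure(g, small) <= lca_closure(g, big)


# ----------------------------------------------------------- extract_subset


def test_all_seeds_is_identity():
    rng = random.Random(42)
    g = random_dag(rng, 25)
    result = extract_subset(g, set(g.terms))
    assert set(result.graph.terms) == set(g.terms)
    assert result.graph.is_a == g.is_a
    assert result.computed_terms == set()


def test_toy_taxonomy_extraction_matches_display_structure(toy_taxonomy, taxa):
    seeds = {taxa["tiger"], taxa["snake"], taxa["silkworm"]}
    result = extract_subset(
        toy_taxonomy,
        seeds,
        ExtractionOptions(
            mode=ExtractionMode.computed_intermediates, include_roots=True
        ),
    )
    assert set(result.graph.terms) == seeds | {
        taxa["amniota"], taxa["bilateria"], taxa["eukaryota"]
    }
    assert result.graph.is_a == {
        (taxa["tiger"], taxa["amniota"]),
        (taxa["snake"], taxa["amniota"]),
        (taxa["amniota"], taxa["bilateria"]),
        (taxa["silkworm"], taxa["bilateria"]),
        (taxa["bilateria"], taxa["eukaryota"]),
    }
    assert result.computed_terms == {
        taxa["amniota"], taxa["bilateria"], taxa["eukaryota"]
    }


@pytest.mark.parametrize("mode", list(ExtractionMode))
@pytest.mark.parametrize("seed", range(8))
def test_reachability_preserved_for_all_seed_pairs(mode, seed):
    rng = random.Random(300 + seed)
    g = random_dag(rng, rng.randint(4, 40))
    seeds = set(rng.sample(sorted(g.terms), min(6, len(g.terms))))
    result = extract_subset(g, seeds, ExtractionOptions(mode=mode))
    for x in seeds:
        for y in seeds:
            if x == y:
                continue
            assert is_ancestor(result.graph, x, y) == is_ancestor(g, x, y)


@pytest.mark.parametrize("seed", range(8))
def test_mode_node_count_ordering(seed):
    rng = random.Random(400 + seed)
    g = random_dag(rng, rng.randint(4, 40))
    seeds = set(rng.sample(sorted(g.terms), min(5, len(g.terms))))
    sizes = {
        mode: len(extract_subset(g, seeds, ExtractionOptions(mode=mode)).graph.terms)
        for mode in ExtractionMode
    }
    assert len(seeds) == sizes[ExtractionMode.no_intermediates]
    assert (
        sizes[ExtractionMode.no_intermediates]
        <= sizes[ExtractionMode.computed_intermediates]
        <= sizes[ExtractionMode.all_intermediates]
    )


@pytest.mark.parametrize("seed", range(10))
def test_computed_mode_equals_steiner_contraction_on_trees(seed):
    rng = random.Random(500 + seed)
    g = random_tree(rng, rng.randint(4, 40))
    seeds = set(rng.sample(sorted(g.terms), min(5, len(g.terms))))
    result = extract_subset(g, seeds)
    expected_nodes = steiner_nodes_on_tree(g, seeds)
    assert set(result.graph.terms) == expected_nodes
    # each kept node links to the nearest kept strict ancestor on the tree path
    for t in expected_nodes:
        kept_anc = ancestors(g, t) & expected_nodes
        expected_parent = set()
        if kept_anc:
            # on a tree ancestors are totally ordered; nearest = deepest
            expected_parent = {
                max(kept_anc, key=lambda a: len(ancestors(g, a)))
            }
        assert {p for (c, p) in result.graph.is_a if c == t} == expected_parent


def test_carry_cross_links_restricted_to_kept_terms():
    g = diamond()
    rel = TermId("RO", "0000087")
    g.add_cross_link(TermId("D", "x"), rel, TermId("D", "y"))
    g.add_cross_link(TermId("D", "x"), rel, TermId("D", "a"))
    seeds = {TermId("D", "x"), TermId("D", "y")}
    kept = extract_subset(
        g, seeds, ExtractionOptions(carry_cross_links=True)
    )
    assert (TermId("D", "x"), rel, TermId("D", "y")) in kept.graph.cross_links
    # D:a and D:b are kept as computed intermediates, so that link survives too
    assert (TermId("D", "x"), rel, TermId("D", "a")) in kept.graph.cross_links
    only_seeds = extract_subset(
        g, seeds,
        ExtractionOptions(
            mode=ExtractionMode.no_intermediates, carry_cross_links=True
        ),
    )
    assert only_seeds.graph.cross_links == {
        (TermId("D", "x"), rel, TermId("D", "y"))
    }


def test_unknown_seed_named_in_error(toy_taxonomy):
    with pytest.raises(UnknownTermError, match="X:404"):
        extract_subset(toy_taxonomy, {TermId("X", "404")})
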