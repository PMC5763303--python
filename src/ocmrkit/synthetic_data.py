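"""Seeded generators for ontology slices and curation tables with known truth.

The DAG is layered — every term's parents come from strictly earlier terms —
so acyclicity holds by construction.  A single integer seed drives named
substreams (``Random(f"{seed}-dag")`` etc.), making every emitted artifact
reproducible byte for byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .curation_ingest import CurationRow, CurationTable
from .ontology_model import RELATION_IDS, OntologyGraph, Term, TermId

__all__ = ["GeneratorParams", "SyntheticTruth", "generate_dag",
           "generate_curation", "generate_dataset"]

TERM_PREFIX = "SYN"
ROLE_PREFIX = "SYNROLE"
AE_PREFIX = "SYNAE"
HAS_ROLE = RELATION_IDS["has_role"]


@dataclass(frozen=True)
class GeneratorParams:
    n_terms: int = 60
    n_roots: int = 1
    max_parents: int = 2
    n_drugs: int = 6
    chemicals_per_drug: tuple[int, int] = (3, 8)
    n_role_terms: int = 2
    role_attachment_depth: int = 2
    ae_sharing_spec: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_terms, self.n_roots, self.max_parents, self.n_drugs,
               self.n_role_terms) < 1:
            raise ValueError("all counts must be positive")
        if self.n_roots > self.n_terms:
            raise ValueError("n_roots cannot exceed n_terms")
        lo, hi = self.chemicals_per_drug
        if not (1 <= lo <= hi):
            raise ValueError("invalid chemicals_per_drug range")
        if self.role_attachment_depth < 0:
            raise ValueError("role_attachment_depth must be >= 0")
        for k, n in self.ae_sharing_spec:
            if k < 1 or n < 1:
                raise ValueError("ae_sharing_spec entries must be positive")
            if k > self.n_drugs:
                raise ValueError(
                    f"cannot share an AE among {k} drugs with only "
                    f"{self.n_drugs} drugs"
                )


@dataclass
class SyntheticTruth:
    """Generator ledger: what was planted, for parameter-recovery tests."""

    role_leaves: dict[TermId, set[TermId]] = field(default_factory=dict)
    role_chemicals: dict[TermId, set[TermId]] = field(default_factory=dict)
    drug_chemicals: dict[str, set[TermId]] = field(default_factory=dict)
    ae_histogram: dict[int, int] = field(default_factory=dict)
    ae_labels_by_k: dict[int, set[str]] = field(default_factory=dict)
    lca_seeds: set[TermId] = field(default_factory=set)
    lca_answer: set[TermId] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "role_leaves": {r.curie: sorted(c.curie for c in s)
                                for r, s in self.role_leaves.items()},
                "role_chemicals": {r.curie: sorted(c.curie for c in s)
                                   for r, s in self.role_chemicals.items()},
                "drug_chemicals": {d: sorted(c.curie for c in s)
                                   for d, s in self.drug_chemicals.items()},
                "ae_histogram": {str(k): n for k, n in sorted(self.ae_histogram.items())},
                "lca_seeds": sorted(t.curie for t in self.lca_seeds),
                "lca_answer": sorted(t.curie for t in self.lca_answer),
            },
            indent=2,
            sort_keys=True,
        )


def _tid(i: int) -> TermId:
    return TermId(TERM_PREFIX, f"{i:07d}")


def generate_dag(p: GeneratorParams) -> tuple[OntologyGraph, SyntheticTruth]:
    """Layered random is_a DAG with planted has_role links and a planted
    branch-point gadget for LCA tests."""
    rng = random.Random(f"{p.seed}-dag")
    g = OntologyGraph()
    truth = SyntheticTruth()

    # track ancestors and depth by construction (independent of the
    # traversal code under test)
    anc: dict[TermId, set[TermId]] = {}
    depth: dict[TermId, int] = {}

    # reserve the last three ids for the LCA gadget when there is room
    gadget = p.n_terms >= p.n_roots + 3
    n_plain = p.n_terms - (3 if gadget else 0)

    ids = [_tid(i + 1) for i in range(p.n_terms)]
    for i in range(n_plain):
        tid = ids[i]
        g.add_term(Term(tid, label=f"term {i + 1}"))
        if i < p.n_roots:
            anc[tid], depth[tid] = set(), 0
            continue
        pool = ids[:i]
        n_par = rng.randint(1, min(p.max_parents, len(pool)))
        parents = rng.sample(pool, n_par)
        anc[tid] = set()
        for parent in parents:
            g.add_is_a(tid, parent)
            anc[tid] |= anc[parent] | {parent}
        depth[tid] = 1 + min(depth[q] for q in parents)

    if gadget:
        branch, x, y = ids[n_plain], ids[n_plain + 1], ids[n_plain + 2]
        g.add_term(Term(branch, label="planted branch point"))
        bp = rng.choice(ids[:n_plain])
        g.add_is_a(branch, bp)
        anc[branch] = anc[bp] | {bp}
        depth[branch] = depth[bp] + 1
        for leaf, name in ((x, "planted leaf x"), (y, "planted leaf y")):
            g.add_term(Term(leaf, label=name))
            g.add_is_a(leaf, branch)
            anc[leaf] = anc[branch] | {branch}
            depth[leaf] = depth[branch] + 1
        truth.lca_seeds = {x, y}
        truth.lca_answer = {branch}

    # role hierarchy under its own root
    role_root = TermId(ROLE_PREFIX, "0000000")
    g.add_term(Term(role_root, label="role"))
    roles = [TermId(ROLE_PREFIX, f"{j:07d}") for j in range(1, p.n_role_terms + 1)]
    for j, role in enumerate(roles, start=1):
        g.add_term(Term(role, label=f"role {j}"))
        g.add_is_a(role, role_root)

    term_ids = set(anc)
    leaves = {t for t in term_ids if not g.children(t)}
    target_depth = p.role_attachment_depth
    candidates = sorted(
        t for t in term_ids
        if depth[t] == target_depth and _leaves_under(g, t, leaves)
    )
    if not candidates:  # fall back to the deepest available attachment points
        best = max((depth[t] for t in term_ids
                    if _leaves_under(g, t, leaves)), default=0)
        candidates = sorted(
            t for t in term_ids
            if depth[t] == best and _leaves_under(g, t, leaves)
        )
    for role in roles:
        attach = rng.choice(candidates)
        g.add_cross_link(attach, HAS_ROLE, role)
        truth.role_leaves[role] = {
            leaf for leaf in leaves if attach in anc[leaf] or attach == leaf
        }
    g.validate()
    return g, truth


def _leaves_under(g: OntologyGraph, t: TermId, leaves: set[TermId]) -> bool:
    stack, seen = [t], set()
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        if cur in leaves:
            return True
        stack.extend(g.children(cur))
    return False


def generate_curation(
    p: GeneratorParams,
    g: OntologyGraph,
    dag_truth: SyntheticTruth | None = None,
) -> tuple[CurationTable, SyntheticTruth]:
    """Drugs with source facts, chemical facts drawn from leaf terms, and AE
    facts realizing the sharing spec exactly."""
    rng = random.Random(f"{p.seed}-curation")
    truth = dag_truth or SyntheticTruth()
    rows: list[CurationRow] = []

    term_ids = sorted(t for t in g.active_terms() if t.prefix == TERM_PREFIX)
    leaf_pool = sorted(t for t in term_ids if not g.children(t))
    if not leaf_pool:
        raise ValueError("graph has no leaf chemicals to draw from")
    roots = sorted(t for t in term_ids if not g.parents(t))

    drugs = [f"synthetic drug {i:02d}" for i in range(1, p.n_drugs + 1)]
    lo, hi = p.chemicals_per_drug
    for drug in drugs:
        rows.append(
            CurationRow(
                drug_label=drug,
                drug_category="synthetic drug category",
                fact_type="source",
                organism=rng.choice(roots),
            )
        )
        n_chem = rng.randint(lo, min(hi, len(leaf_pool)))
        chems = sorted(rng.sample(leaf_pool, n_chem))
        truth.drug_chemicals[drug] = set(chems)
        for chem in chems:
            rows.append(
                CurationRow(
                    drug_label=drug,
                    drug_category="synthetic drug category",
                    fact_type="chemical",
                    chemical_label=f"chemical {chem.local}",
                    chemical_id=chem,
                )
            )

    used_chems = set().union(*truth.drug_chemicals.values())
    for role, leaves in truth.role_leaves.items():
        truth.role_chemicals[role] = leaves & used_chems

    ae_no = 0
    for k, n_aes in p.ae_sharing_spec:
        truth.ae_histogram[k] = truth.ae_histogram.get(k, 0) + n_aes
        for _ in range(n_aes):
            ae_no += 1
            label = f"synthetic AE {ae_no:03d}"
            ae_id = TermId(AE_PREFIX, f"{ae_no:07d}")
            truth.ae_labels_by_k.setdefault(k, set()).add(label.casefold())
            for drug in rng.sample(drugs, k):
                rows.append(
                    CurationRow(
                        drug_label=drug,
                        drug_category="synthetic drug category",
                        fact_type="ae",
                        ae_label=label,
                        ae_id=ae_id,
                    )
                )
    return CurationTable(rows), truth


def generate_dataset(
    p: GeneratorParams,
) -> tuple[OntologyGraph, CurationTable, SyntheticTruth]:
    """Convenience wrapper chaining :func:`generate_dag` and
    :func:`generate_curation` on one truth ledger."""
    g, truth = generate_dag(p)
    ct, truth = generate_curation(p, g, truth)
    return g, ct, truth
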