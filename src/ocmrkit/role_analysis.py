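"""Role-based chemical classification and structural-branch analyses.

A drug-ingredient chemical bears a role when any of its is_a ancestors (or
itself) carries a ``has_role`` assertion whose target is the queried role or
one of the role's descendants — i.e. subsumption is applied on both the
chemical side and the role side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .kg_builder import KnowledgeGraph, RelationConfig
from .ontology_model import (
    OntologyGraph,
    TermId,
    UnknownTermError,
    descendants,
)

__all__ = [
    "RoleReport",
    "BranchReport",
    "ingredient_chemicals",
    "chemicals_with_role",
    "role_overlap",
    "branch_members",
    "role_report",
    "branch_report",
]


def ingredient_chemicals(kg: KnowledgeGraph, rc: RelationConfig | None = None) -> set[TermId]:
    """All chemicals referenced as drug ingredients (objects of has_part)."""
    rc = rc or RelationConfig()
    return {tr.object for tr in kg.matching(predicate=rc.has_part)}


def chemicals_with_role(
    kg: KnowledgeGraph, role: TermId, rc: RelationConfig | None = None
) -> set[TermId]:
    """Ingredient chemicals bearing ``role`` under two-sided subsumption."""
    rc = rc or RelationConfig()
    if role not in kg.terms():
        warnings.warn(f"role {role.curie} not present in the knowledge graph")
        return set()
    role_and_descendants = kg.subclasses(role, reflexive=True)
    bearers = {
        tr.subject
        for tr in kg.matching(predicate=rc.has_role)
        if tr.object in role_and_descendants
    }
    out: set[TermId] = set()
    for chem in ingredient_chemicals(kg, rc):
        if kg.superclasses(chem, reflexive=True) & bearers:
            out.add(chem)
    return out


def role_overlap(
    kg: KnowledgeGraph, r1: TermId, r2: TermId, rc: RelationConfig | None = None
) -> tuple[set[TermId], set[TermId], set[TermId]]:
    """Partition of the union of two role sets: (only r1, only r2, both)."""
    s1 = chemicals_with_role(kg, r1, rc)
    s2 = chemicals_with_role(kg, r2, rc)
    return s1 - s2, s2 - s1, s1 & s2


def branch_members(
    g: OntologyGraph, branch: TermId, chems: set[TermId]
) -> set[TermId]:
    """Members of ``chems`` inside the is_a branch rooted at ``branch``."""
    if branch not in g.terms:
        raise UnknownTermError(branch)
    return set(chems) & (descendants(g, branch) | {branch})


@dataclass
class RoleReport:
    role_sets: dict[TermId, set[TermId]] = field(default_factory=dict)
    pairwise_both: dict[tuple[TermId, TermId], set[TermId]] = field(default_factory=dict)
    per_drug: dict[str, dict[TermId, set[TermId]]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "roles": {
                r.curie: sorted(c.curie for c in chems)
                for r, chems in self.role_sets.items()
            },
            "pairwise_both": {
                f"{a.curie}&{b.curie}": sorted(c.curie for c in chems)
                for (a, b), chems in self.pairwise_both.items()
            },
            "per_drug": {
                drug: {
                    r.curie: sorted(c.curie for c in chems)
                    for r, chems in roles.items()
                }
                for drug, roles in self.per_drug.items()
            },
        }


@dataclass
class BranchReport:
    branch_sets: dict[TermId, set[TermId]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            b.curie: sorted(c.curie for c in chems)
            for b, chems in self.branch_sets.items()
        }


def role_report(
    kg: KnowledgeGraph, roles: list[TermId], rc: RelationConfig | None = None
) -> RoleReport:
    """Per-role chemical sets, pairwise intersections and per-drug breakdown."""
    rc = rc or RelationConfig()
    report = RoleReport()
    for role in roles:
        report.role_sets[role] = chemicals_with_role(kg, role, rc)
    for i, a in enumerate(roles):
        for b in roles[i + 1:]:
            report.pairwise_both[(a, b)] = report.role_sets[a] & report.role_sets[b]
    for tr in kg.matching(predicate=rc.has_part):
        drug_label = kg.labels.get(tr.subject, tr.subject.curie)
        drug_roles = report.per_drug.setdefault(drug_label, {})
        for role in roles:
            if tr.object in report.role_sets[role]:
                drug_roles.setdefault(role, set()).add(tr.object)
    return report


def branch_report(
    g: OntologyGraph, branches: list[TermId], chems: set[TermId]
) -> BranchReport:
    report = BranchReport()
    for branch in branches:
        report.branch_sets[branch] = branch_members(g, branch, chems)
    return report
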