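"""Adverse-event profiling: uniqueness, cross-drug sharing and top-level
classification against an AE ontology slice.

Sharing is computed on normalized AE labels by default (some curated AEs lack
ontology ids); CURIE-level grouping is available via ``key="curie"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .curation_ingest import CurationTable, normalize_label
from .ontology_model import (
    OntologyGraph,
    TermId,
    UnknownTermError,
    ancestors,
)

__all__ = [
    "AEProfile",
    "TopLevelAEReport",
    "ae_profile",
    "sharing_histogram",
    "aes_shared_by_at_least",
    "top_level_ae_classes",
]


@dataclass
class AEProfile:
    """Map AE key -> set of drug labels reporting it, plus row tallies."""

    drugs_by_ae: dict[str, set[str]] = field(default_factory=dict)
    total_ae_rows: int = 0
    total_drug_ae_pairs: int = 0

    @property
    def unique_aes(self) -> int:
        return len(self.drugs_by_ae)


def ae_profile(ct: CurationTable, key: str = "label") -> AEProfile:
    """Group AE facts by normalized label (or CURIE); per-drug duplicates
    count once per drug."""
    if key not in ("label", "curie"):
        raise ValueError("key must be 'label' or 'curie'")
    profile = AEProfile()
    for row in ct.rows:
        if row.fact_type != "ae":
            continue
        profile.total_ae_rows += 1
        if key == "label":
            if not row.ae_label:
                continue
            ae_key = normalize_label(row.ae_label)
        else:
            if row.ae_id is None:
                continue
            ae_key = row.ae_id.curie
        profile.drugs_by_ae.setdefault(ae_key, set()).add(
            normalize_label(row.drug_label)
        )
    profile.total_drug_ae_pairs = sum(
        len(drugs) for drugs in profile.drugs_by_ae.values()
    )
    return profile


def sharing_histogram(p: AEProfile) -> dict[int, set[str]]:
    """Partition AEs by the exact number of drugs reporting them."""
    hist: dict[int, set[str]] = {}
    for ae, drugs in p.drugs_by_ae.items():
        hist.setdefault(len(drugs), set()).add(ae)
    return hist


def aes_shared_by_at_least(p: AEProfile, k: int) -> set[str]:
    if k < 1:
        raise ValueError("k must be >= 1")
    return {ae for ae, drugs in p.drugs_by_ae.items() if len(drugs) >= k}


@dataclass
class TopLevelAEReport:
    by_class: dict[TermId, set[TermId]] = field(default_factory=dict)
    unassigned: set[TermId] = field(default_factory=set)


def top_level_ae_classes(
    g_oae: OntologyGraph, aes: set[TermId], designated: set[TermId]
) -> TopLevelAEReport:
    """Assign each AE to every designated class among its ancestors-or-self.

    An AE under two designated branches appears in both groups (the AE
    hierarchy is a DAG); AEs under none are reported separately.
    """
    for d in designated:
        if d not in g_oae.terms:
            raise UnknownTermError(d)
    report = TopLevelAEReport(by_class={d: set() for d in designated})
    for ae in sorted(aes):
        if ae not in g_oae.terms:
            raise UnknownTermError(ae)
        hits = (ancestors(g_oae, ae) | {ae}) & set(designated)
        if hits:
            for h in hits:
                report.by_class[h].add(ae)
        else:
            report.unassigned.add(ae)
    return report
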