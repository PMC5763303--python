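"""Parsing and validation of the drug-centric curation table.

The table is one long-format TSV: one row per (drug, fact).  A row carries
exactly one fact kind — ``source`` (organism/anatomy), ``chemical``
(ingredient label, optional ChEBI CURIE, optional curator role assignments)
or ``ae`` (adverse event label, optional OAE CURIE).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Mapping

from .ontology_model import OntologyGraph, TermId

__all__ = [
    "CurationRow",
    "CurationTable",
    "ValidationReport",
    "CurationError",
    "KNOWN_ROLES",
    "COLUMNS",
    "normalize_label",
    "parse_curation_table",
    "write_curation_table",
    "validate_curation",
    "ingredient_entries",
]

COLUMNS = (
    "drug",
    "category",
    "fact_type",
    "organism_id",
    "anatomy_id",
    "chemical_label",
    "chemical_id",
    "roles",
    "ae_label",
    "ae_id",
)

FACT_TYPES = ("source", "chemical", "ae")

#: curator role names accepted in the ``roles`` column
KNOWN_ROLES = ("anti-inflammatory", "antineoplastic")


class CurationError(ValueError):
    def __init__(self, message: str, row_no: int | None = None):
        self.row_no = row_no
        if row_no is not None:
            message = f"row {row_no}: {message}"
        super().__init__(message)


def normalize_label(s: str) -> str:
    """Trim, collapse internal whitespace, casefold, and drop a trailing
    'TCD' drug-name suffix."""
    out = " ".join(s.split()).casefold()
    if out.endswith(" tcd"):
        out = out[: -len(" tcd")].rstrip()
    return out


@dataclass
class CurationRow:
    drug_label: str
    drug_category: str = ""
    fact_type: str = "chemical"
    organism: TermId | None = None
    anatomy: TermId | None = None
    chemical_label: str | None = None
    chemical_id: TermId | None = None
    roles: frozenset[str] = frozenset()
    ae_label: str | None = None
    ae_id: TermId | None = None

    def __post_init__(self) -> None:
        if not self.drug_label.strip():
            raise CurationError("drug label must be nonempty")
        if self.fact_type not in FACT_TYPES:
            raise CurationError(f"unknown fact_type {self.fact_type!r}")
        has_chem = bool(self.chemical_label or self.chemical_id)
        has_ae = bool(self.ae_label or self.ae_id)
        has_src = bool(self.organism or self.anatomy)
        if sum([has_chem, has_ae, has_src]) > 1:
            raise CurationError("a row may carry at most one fact kind")
        if self.roles and not has_chem:
            raise CurationError("roles are only valid on chemical rows")
        kind = {"source": has_src, "chemical": has_chem, "ae": has_ae}
        carried = [k for k, v in kind.items() if v]
        if carried and carried != [self.fact_type]:
            raise CurationError(
                f"fact_type={self.fact_type} but row carries a {carried[0]} fact"
            )


@dataclass
class CurationTable:
    rows: list[CurationRow] = field(default_factory=list)

    @property
    def drugs(self) -> set[str]:
        return {r.drug_label for r in self.rows}

    def rows_of(self, fact_type: str) -> list[CurationRow]:
        return [r for r in self.rows if r.fact_type == fact_type]


def _parse_optional_id(value: str, row_no: int, column: str) -> TermId | None:
    value = value.strip()
    if not value:
        return None
    try:
        return TermId.parse(value)
    except ValueError as exc:
        raise CurationError(f"malformed CURIE in {column}: {value!r}", row_no) from exc


def parse_curation_table(path) -> CurationTable:
    """Read the long-format TSV; '#'-prefixed lines are comments.

    The ``drug`` column may list several ';'-separated drug labels (printed
    reference tables assign one ingredient entry to several drugs); such a
    line expands to one row per drug so every parsed row carries exactly one
    (drug, fact) pair.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None:
        return CurationTable()
    missing = [c for c in COLUMNS if c not in reader.fieldnames]
    if missing:
        raise CurationError(f"missing column(s): {', '.join(missing)}")
    rows: list[CurationRow] = []
    for row_no, rec in enumerate(reader, start=2):
        get = lambda c: (rec.get(c) or "").strip()  # noqa: E731
        fact_type = get("fact_type")
        if fact_type not in FACT_TYPES:
            raise CurationError(f"unknown fact_type {fact_type!r}", row_no)
        roles = frozenset(
            r.strip() for r in get("roles").split(";") if r.strip()
        )
        unknown_roles = roles - set(KNOWN_ROLES)
        if unknown_roles:
            raise CurationError(
                f"unknown role(s): {', '.join(sorted(unknown_roles))}", row_no
            )
        drug_labels = [d.strip() for d in get("drug").split(";") if d.strip()]
        if not drug_labels:
            raise CurationError("drug label must be nonempty", row_no)
        try:
            for drug_label in drug_labels:
                rows.append(
                    CurationRow(
                        drug_label=drug_label,
                        drug_category=get("category"),
                        fact_type=fact_type,
                        organism=_parse_optional_id(get("organism_id"), row_no, "organism_id"),
                        anatomy=_parse_optional_id(get("anatomy_id"), row_no, "anatomy_id"),
                        chemical_label=get("chemical_label") or None,
                        chemical_id=_parse_optional_id(get("chemical_id"), row_no, "chemical_id"),
                        roles=roles,
                        ae_label=get("ae_label") or None,
                        ae_id=_parse_optional_id(get("ae_id"), row_no, "ae_id"),
                    )
                )
        except CurationError as exc:
            if exc.row_no is None:
                raise CurationError(str(exc), row_no) from exc
            raise
    return CurationTable(rows)


def write_curation_table(ct: CurationTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for r in ct.rows:
            writer.writerow(
                [
                    r.drug_label,
                    r.drug_category,
                    r.fact_type,
                    r.organism.curie if r.organism else "",
                    r.anatomy.curie if r.anatomy else "",
                    r.chemical_label or "",
                    r.chemical_id.curie if r.chemical_id else "",
                    ";".join(sorted(r.roles)),
                    r.ae_label or "",
                    r.ae_id.curie if r.ae_id else "",
                ]
            )


@dataclass
class ValidationReport:
    per_drug: dict[str, dict[str, int]] = field(default_factory=dict)
    unique_chemical_ids: int = 0
    total_chemical_rows: int = 0
    chemical_rows_with_id: int = 0
    distinct_chemical_entries: int = 0
    unique_ae_labels: int = 0
    total_ae_rows: int = 0
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_drug": self.per_drug,
                "unique_chemical_ids": self.unique_chemical_ids,
                "total_chemical_rows": self.total_chemical_rows,
                "chemical_rows_with_id": self.chemical_rows_with_id,
                "distinct_chemical_entries": self.distinct_chemical_entries,
                "unique_ae_labels": self.unique_ae_labels,
                "total_ae_rows": self.total_ae_rows,
                "errors": self.errors,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )


# ontology name expected to declare each CURIE prefix, when that slice is given
_PREFIX_ONTOLOGY = {
    "CHEBI": "chebi",
    "OAE": "oae",
    "NCBITaxon": "ncbitaxon",
    "PO": "po",
    "UBERON": "uberon",
}


def validate_curation(
    ct: CurationTable, ontologies: Mapping[str, OntologyGraph] | None = None
) -> ValidationReport:
    """Tally per-drug and global counts and check CURIEs against any supplied
    ontology slices.

    Unique chemical counts deduplicate by CURIE; unique AE counts deduplicate
    by normalized label.  A CURIE absent from its supplied ontology is a
    warning, not an error.  A drug with no source fact is reported as a
    warning (printed reference tables often omit sources).
    """
    ontologies = ontologies or {}
    report = ValidationReport()
    chem_ids: set[TermId] = set()
    ae_labels: set[str] = set()
    for r in ct.rows:
        d = report.per_drug.setdefault(
            r.drug_label,
            {"chemicals": 0, "chemicals_with_id": 0, "aes": 0, "sources": 0},
        )
        if r.fact_type == "chemical":
            report.total_chemical_rows += 1
            d["chemicals"] += 1
            if r.chemical_id is not None:
                report.chemical_rows_with_id += 1
                d["chemicals_with_id"] += 1
                chem_ids.add(r.chemical_id)
                _check_in_ontology(r.chemical_id, ontologies, report)
            else:
                report.warnings.append(
                    f"chemical {r.chemical_label!r} of {r.drug_label!r} has no CURIE"
                )
        elif r.fact_type == "ae":
            report.total_ae_rows += 1
            d["aes"] += 1
            if r.ae_label:
                ae_labels.add(normalize_label(r.ae_label))
            if r.ae_id is not None:
                _check_in_ontology(r.ae_id, ontologies, report)
        else:
            d["sources"] += 1
            for t in (r.organism, r.anatomy):
                if t is not None:
                    _check_in_ontology(t, ontologies, report)
    for drug, counts in report.per_drug.items():
        if counts["sources"] == 0:
            report.warnings.append(f"drug {drug!r} has no source fact")
    report.unique_chemical_ids = len(chem_ids)
    report.unique_ae_labels = len(ae_labels)
    report.distinct_chemical_entries = ingredient_entries(ct)
    return report


def ingredient_entries(ct: CurationTable, require_roles: bool = False) -> int:
    """Count distinct ingredient entries among chemical rows.

    An entry is one (chemical, role-assignment) pair: a chemical listed under
    several drugs with the same role assignment is one entry, but the same
    chemical appearing again with a different role assignment counts again —
    this is how printed per-role reference tables enumerate their rows.
    """
    entries: set[tuple[str, frozenset[str]]] = set()
    for r in ct.rows:
        if r.fact_type != "chemical":
            continue
        if require_roles and not r.roles:
            continue
        key = r.chemical_id.curie if r.chemical_id else normalize_label(
            r.chemical_label or ""
        )
        entries.add((key, r.roles))
    return len(entries)


def _check_in_ontology(
    t: TermId, ontologies: Mapping[str, OntologyGraph], report: ValidationReport
) -> None:
    name = _PREFIX_ONTOLOGY.get(t.prefix, t.prefix.lower())
    g = ontologies.get(name)
    if g is not None and t not in g:
        report.warnings.append(f"{t.curie} not found in ontology {name!r}")
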