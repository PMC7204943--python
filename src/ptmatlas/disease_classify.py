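"""Trichotomous disease classification of proteins: CVD / OD / ND.

Each protein in the study universe is assigned exactly one category from
its disease associations: CVD when any association matches the curated
cardiovascular term list (CVD takes priority - a CVD protein may carry
other-disease associations too), OD when it has associations but none
cardiovascular, ND when it has no known association at all.

Term matching is case-insensitive exact match on whitespace-normalised
disease names; a term prefixed with ``~`` matches as a substring instead.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_integration import DiseaseAssociationRaw

logger = logging.getLogger("ptmatlas.disease")

CATEGORIES = ("CVD", "OD", "ND")


def normalize_disease_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


@dataclass(frozen=True)
class CVDTermList:
    """Curated cardiovascular terms: exact names plus substring patterns."""

    exact: frozenset[str]
    substrings: tuple[str, ...]

    def matches(self, disease_name: str) -> list[str]:
        name = normalize_disease_name(disease_name)
        hits = []
        if name in self.exact:
            hits.append(name)
        for pat in self.substrings:
            if pat in name:
                hits.append("~" + pat)
        return hits

    def __len__(self) -> int:
        return len(self.exact) + len(self.substrings)


def parse_cvd_terms(lines: Iterable[str]) -> CVDTermList:
    exact: set[str] = set()
    subs: list[str] = []
    for line in lines:
        term = line.strip()
        if not term or term.startswith("#"):
            continue
        if term.startswith("~"):
            subs.append(normalize_disease_name(term[1:]))
        else:
            exact.add(normalize_disease_name(term))
    return CVDTermList(exact=frozenset(exact), substrings=tuple(subs))


def load_cvd_terms(path: str | Path) -> CVDTermList:
    with open(path, encoding="utf-8") as fh:
        return parse_cvd_terms(fh)


def default_cvd_terms() -> CVDTermList:
    """The starter cardiovascular term list shipped with the package."""
    from importlib.resources import files

    text = files("ptmatlas.data").joinpath("cvd_terms.txt").read_text(encoding="utf-8")
    return parse_cvd_terms(text.splitlines())


@dataclass(frozen=True)
class DiseaseCategoryAssignment:
    accession: str
    category: str  # CVD | OD | ND
    matched_cvd_terms: frozenset[str]
    n_associations: int

    def __post_init__(self) -> None:
        if (self.category == "CVD") != bool(self.matched_cvd_terms):
            raise ValueError("CVD category iff matched terms non-empty")
        if (self.category == "ND") != (self.n_associations == 0):
            raise ValueError("ND category iff zero associations")


def _associations_by_protein(
    associations: Iterable[DiseaseAssociationRaw],
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for assoc in associations:
        out.setdefault(assoc.gene_or_accession, set()).add(assoc.disease_name)
    return out


def classify(
    associations: Iterable[DiseaseAssociationRaw],
    cvd_terms: CVDTermList,
    universe: Iterable[str],
) -> list[DiseaseCategoryAssignment]:
    """Assign every protein in ``universe`` to exactly one of CVD / OD / ND.

    Associations must already be keyed by accession (apply the gene-symbol
    mapping first when the source table is gene-keyed).
    """
    if len(cvd_terms) == 0:
        logger.warning("empty CVD term list: all diseased proteins will be OD")
    by_protein = _associations_by_protein(associations)
    out: list[DiseaseCategoryAssignment] = []
    for acc in sorted(set(universe)):
        diseases = by_protein.get(acc, set())
        matched: set[str] = set()
        for d in diseases:
            matched.update(cvd_terms.matches(d))
        if matched:
            category = "CVD"
        elif diseases:
            category = "OD"
        else:
            category = "ND"
        out.append(
            DiseaseCategoryAssignment(
                accession=acc,
                category=category,
                matched_cvd_terms=frozenset(matched),
                n_associations=len(diseases),
            )
        )
    return out


def category_exclusives(
    assignments: Sequence[DiseaseCategoryAssignment],
    associations: Iterable[DiseaseAssociationRaw],
    cvd_terms: CVDTermList,
) -> set[str]:
    """CVD proteins whose *every* association is a cardiovascular term."""
    by_protein = _associations_by_protein(associations)
    exclusives: set[str] = set()
    for a in assignments:
        if a.category != "CVD":
            continue
        diseases = by_protein.get(a.accession, set())
        if diseases and all(cvd_terms.matches(d) for d in diseases):
            exclusives.add(a.accession)
    return exclusives


def category_counts(assignments: Sequence[DiseaseCategoryAssignment]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return counts


def category_of(assignments: Sequence[DiseaseCategoryAssignment]) -> Mapping[str, str]:
    return {a.accession: a.category for a in assignments}
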