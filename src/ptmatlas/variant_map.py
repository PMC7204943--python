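"""Amino-acid variants mapped into PTM motifs (motif-associated variants).

A variant record is a single-residue substitution in protein coordinates.
A variant lying within the +/-7-residue motif of a cataloged PTM site is a
*motif-associated variant* (MAV); a variant near several sites yields one
MAV per anchoring site, while headline totals count each distinct variant
once.  Variant classifications follow the three-class convention of
curated variant resources: disease (LP/P), polymorphism (LB/B) and
unclassified (US).
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1

from .io_integration import ParseError, ProteinRecord, _iter_rows, _parse_int
from .motif_hotspot import DEFAULT_FLANK, HotspotRegion
from .ptm_catalog import PTMSite

logger = logging.getLogger("ptmatlas.variants")

CLASSIFICATIONS = ("disease", "polymorphism", "unclassified")

# Humsavar-era and modern ACMG-style labels all collapse to three classes
_CLASS_ALIASES = {
    "disease": "disease",
    "lp/p": "disease",
    "likely pathogenic": "disease",
    "pathogenic": "disease",
    "polymorphism": "polymorphism",
    "lb/b": "polymorphism",
    "likely benign": "polymorphism",
    "benign": "polymorphism",
    "unclassified": "unclassified",
    "us": "unclassified",
    "uncertain significance": "unclassified",
}

_THREE_TO_ONE = {k.capitalize(): v for k, v in protein_letters_3to1.items()}
_NOTATION_RE = re.compile(r"^p\.([A-Za-z]{3})(\d+)([A-Za-z]{3})$")


def normalize_classification(label: str) -> str:
    cls = _CLASS_ALIASES.get(label.strip().lower())
    return cls if cls is not None else "unclassified"


def parse_variant_notation(text: str) -> tuple[int, str, str]:
    """Parse ``p.Trp26Cys``-style substitution notation into
    (position, ref, alt) one-letter form."""
    m = _NOTATION_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse variant notation {text!r}")
    ref3, pos, alt3 = m.group(1).capitalize(), int(m.group(2)), m.group(3).capitalize()
    try:
        ref, alt = _THREE_TO_ONE[ref3], _THREE_TO_ONE[alt3]
    except KeyError as exc:
        raise ParseError(f"unknown amino-acid code {exc.args[0]!r} in {text!r}") from None
    if ref == alt:
        raise ParseError(f"reference equals alternate in {text!r}")
    return pos, ref, alt


@dataclass(frozen=True)
class VariantRecord:
    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    classification: str  # disease | polymorphism | unclassified

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt residues must differ")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")

    @property
    def key(self) -> tuple:
        return (self.accession, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class MotifAssociatedVariant:
    """One (variant, anchoring site) pair with |offset| <= flank."""

    variant: VariantRecord
    site_accession: str
    site_position: int
    offset: int
    at_site: bool
    site_is_crosstalk: bool
    site_types: frozenset[str]
    ref_matches_sequence: bool = True


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant table: either columns accession, position, ref, alt,
    class, or columns accession, change (``p.Trp26Cys`` notation), class."""
    path = Path(path)
    out: list[VariantRecord] = []
    header = None
    for lineno, fields in _iter_rows(path):
        if header is None:
            header = {name: i for i, name in enumerate(fields)}
            if "accession" not in header:
                raise ParseError(f"{path}: missing accession column")
            notation = "change" in header
            if not notation and "position" not in header:
                raise ParseError(f"{path}: need either 'change' or 'position' columns")
            continue
        cls = normalize_classification(
            fields[header["class"]] if "class" in header else "unclassified"
        )
        if notation:
            pos, ref, alt = parse_variant_notation(fields[header["change"]])
        else:
            pos = _parse_int(fields[header["position"]], path, lineno)
            ref, alt = fields[header["ref"]], fields[header["alt"]]
        out.append(VariantRecord(fields[header["accession"]], pos, ref, alt, cls))
    return out


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(v.accession, v.position, v.ref_aa, v.alt_aa, v.classification) for v in variants],
        columns=["accession", "position", "ref", "alt", "class"],
    )
    from .io_integration import write_table

    write_table(frame, path)


def map_mavs(
    variants: Sequence[VariantRecord],
    catalog: Iterable[PTMSite],
    flank: int = DEFAULT_FLANK,
    proteome: Mapping[str, ProteinRecord] | None = None,
) -> tuple[list[MotifAssociatedVariant], pd.DataFrame]:
    """Map variants into PTM motifs.

    Returns (mavs, variant_flags).  ``mavs`` holds one record per
    (variant, site) pair with |variant.position - site.position| <= flank.
    ``variant_flags`` has one row per distinct variant with ``is_mav`` and
    ``ref_matches`` columns; reference-residue disagreements with the
    sequence are logged and flagged, never corrected.
    """
    sites_by_protein: dict[str, list[PTMSite]] = defaultdict(list)
    for s in catalog:
        sites_by_protein[s.accession].append(s)
    for lst in sites_by_protein.values():
        lst.sort(key=lambda s: s.position)

    mavs: list[MotifAssociatedVariant] = []
    flag_rows = []
    n_mismatch = 0
    seen: set[tuple] = set()
    for v in variants:
        if v.key in seen:
            continue
        seen.add(v.key)
        ref_ok = True
        if proteome is not None and v.accession in proteome:
            seq = proteome[v.accession].sequence
            if v.position <= len(seq) and seq[v.position - 1] != v.ref_aa:
                ref_ok = False
                n_mismatch += 1
        is_mav = False
        for s in sites_by_protein.get(v.accession, ()):
            offset = v.position - s.position
            if abs(offset) <= flank:
                is_mav = True
                mavs.append(
                    MotifAssociatedVariant(
                        variant=v,
                        site_accession=s.accession,
                        site_position=s.position,
                        offset=offset,
                        at_site=offset == 0,
                        site_is_crosstalk=s.is_crosstalk,
                        site_types=frozenset(s.types),
                        ref_matches_sequence=ref_ok,
                    )
                )
        flag_rows.append(
            (v.accession, v.position, v.ref_aa, v.alt_aa, v.classification, is_mav, ref_ok)
        )
    if n_mismatch:
        logger.info("map_mavs: %d variants disagree with the sequence reference residue",
                    n_mismatch)
    flags = pd.DataFrame(
        flag_rows,
        columns=["accession", "position", "ref", "alt", "class", "is_mav", "ref_matches"],
    )
    return mavs, flags


def _position_in_regions(pos: int, regions: Sequence[HotspotRegion]) -> bool:
    return any(r.start <= pos <= r.end for r in regions)


def mav_summaries(
    mavs: Sequence[MotifAssociatedVariant],
    variant_flags: pd.DataFrame,
    categories: Mapping[str, str] | None = None,
    site_labels: Mapping[tuple[str, int], str] | None = None,
    hotspot_regions: Mapping[str, Mapping[str, Sequence[HotspotRegion]]] | None = None,
    flank: int = DEFAULT_FLANK,
    hotspot_report_threshold: int = 10,
) -> dict[str, pd.DataFrame]:
    """The MAV summary tables.

    Returns a dict of DataFrames:

    * ``by_class`` - distinct MAV variants per classification (each variant
      counted once via its is_mav flag).
    * ``by_disease_category`` - distinct MAV variants per protein disease
      category (requires ``categories``).
    * ``positional`` - offset histogram -flank..+flank split by
      classification, in both counting conventions: ``n_pairs`` counts
      variant-site pairs, ``n_distinct_variants`` counts each variant once
      per offset.
    * ``crosstalk_split`` - per PTM type, the proportion of MAV pairs
      anchored at crosstalk vs non-crosstalk sites (rows sum to 1).
    * ``by_structural_category`` - MAV pairs per disorder label of the
      anchoring site (requires ``site_labels``).
    * ``hotspot_overlap`` - per protein, distinct MAV variants inside
      stitched ptm / crosstalk hotspot regions, with a ``meets_threshold``
      flag at the configured report threshold (requires
      ``hotspot_regions`` as accession -> {"ptm": [...], "crosstalk": [...]}).
    """
    tables: dict[str, pd.DataFrame] = {}

    mav_variants = variant_flags[variant_flags["is_mav"]]
    by_class = mav_variants.groupby("class").size()
    tables["by_class"] = pd.DataFrame(
        [(c, int(by_class.get(c, 0))) for c in CLASSIFICATIONS],
        columns=["class", "n_variants"],
    )

    if categories is not None:
        counts: Counter[str] = Counter()
        for row in mav_variants.itertuples(index=False):
            counts[categories.get(row.accession, "ND")] += 1
        tables["by_disease_category"] = pd.DataFrame(
            sorted(counts.items()), columns=["category", "n_variants"]
        )

    # positional histogram, both counting conventions
    pair_counts: dict[tuple[int, str], int] = Counter()
    distinct: dict[tuple[int, str], set] = defaultdict(set)
    for m in mavs:
        key = (m.offset, m.variant.classification)
        pair_counts[key] += 1
        distinct[key].add(m.variant.key)
    rows = []
    for cls in CLASSIFICATIONS:
        for d in range(-flank, flank + 1):
            rows.append(
                (d, cls, pair_counts.get((d, cls), 0), len(distinct.get((d, cls), ())))
            )
    tables["positional"] = pd.DataFrame(
        rows, columns=["offset", "class", "n_pairs", "n_distinct_variants"]
    )

    # per-type crosstalk vs non-crosstalk anchoring (pair counting)
    type_counts: dict[str, Counter] = defaultdict(Counter)
    for m in mavs:
        for t in m.site_types:
            type_counts[t]["crosstalk" if m.site_is_crosstalk else "non_crosstalk"] += 1
    rows = []
    for t in sorted(type_counts):
        c = type_counts[t]
        total = c["crosstalk"] + c["non_crosstalk"]
        rows.append(
            (t, total, c["crosstalk"] / total, c["non_crosstalk"] / total)
        )
    tables["crosstalk_split"] = pd.DataFrame(
        rows, columns=["type", "n_pairs", "frac_crosstalk", "frac_non_crosstalk"]
    )

    if site_labels is not None:
        struct: Counter[str] = Counter()
        for m in mavs:
            struct[site_labels.get((m.site_accession, m.site_position), "unknown")] += 1
        tables["by_structural_category"] = pd.DataFrame(
            sorted(struct.items()), columns=["structural_category", "n_pairs"]
        )

    if hotspot_regions is not None:
        per_protein: dict[str, dict[str, set]] = defaultdict(
            lambda: {"ptm": set(), "crosstalk": set()}
        )
        for m in mavs:
            regions = hotspot_regions.get(m.site_accession)
            if not regions:
                continue
            for kind in ("ptm", "crosstalk"):
                if _position_in_regions(m.variant.position, regions.get(kind, ())):
                    per_protein[m.site_accession][kind].add(m.variant.key)
        rows = []
        for acc in sorted(per_protein):
            n_ptm = len(per_protein[acc]["ptm"])
            n_ct = len(per_protein[acc]["crosstalk"])
            rows.append(
                (acc, n_ptm, n_ct,
                 n_ptm >= hotspot_report_threshold and n_ct >= hotspot_report_threshold)
            )
        tables["hotspot_overlap"] = pd.DataFrame(
            rows,
            columns=["accession", "n_mavs_in_ptm_hotspots",
                     "n_mavs_in_crosstalk_hotspots", "meets_threshold"],
        )
    return tables
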