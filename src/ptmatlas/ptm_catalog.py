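"""PTM name canonicalisation, cross-source site deduplication, and in-situ
crosstalk detection.

The atom of the analysis is the deduplicated (protein, position) locus: all
raw records from all source databases that name the same residue of the same
protein collapse into one :class:`PTMSite` carrying the union of canonical
modification types and the union of source attributions.  A site carrying
two or more distinct canonical types is an *in-situ crosstalk* site - the
types compete for the same residue (e.g. acetylation vs ubiquitination on
one lysine).

Canonical type names are lowercase; chemically-specific raw names collapse
onto the umbrella type (phosphoserine/-threonine/-tyrosine ->
phosphorylation; mono-/di-/tri-methyllysine -> methylation), with the
verbatim names retained in ``raw_names``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_integration import ProteinRecord, PTMSiteRaw, read_table

logger = logging.getLogger("ptmatlas.catalog")

# Default raw-name -> canonical-type mapping: ordered (pattern, canonical)
# pairs, matched case-insensitively as regex search.  Covers the umbrella
# types used throughout the analysis; anything unmatched passes through
# lowercased so rare modification names are never silently lost.
DEFAULT_NAME_MAP: tuple[tuple[str, str], ...] = (
    (r"phospho", "phosphorylation"),
    (r"acetyl", "acetylation"),
    (r"ubiquit", "ubiquitination"),
    (r"sumo", "sumoylation"),
    (r"methyl", "methylation"),  # mono-, di- and tri- collapse here
    (r"malonyl", "malonylation"),
    (r"succinyl", "succinylation"),
    (r"glutaryl", "glutarylation"),
    (r"butyryl", "butyrylation"),
    (r"crotonyl", "crotonylation"),
    (r"n-?linked|n-?glyco", "n-glycosylation"),
    (r"o-?linked|o-?glyco|o-?glcnac|o-?galnac", "o-glycosylation"),
    (r"s-?nitros", "s-nitrosylation"),
    (r"glutathio", "glutathionylation"),
    (r"sulfo|sulfat", "sulfation"),
    (r"deamidat", "deamidation"),
)

_unmapped_seen: set[str] = set()


def load_ptm_name_map(path) -> tuple[tuple[str, str], ...]:
    """Load a two-column (pattern, canonical) mapping table from TSV."""
    frame = read_table(path)
    return tuple(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def canonicalize_ptm_name(
    raw_name: str,
    mapping_table: Sequence[tuple[str, str]] | None = None,
) -> str:
    """Map a verbatim modification name to its canonical type.

    Matching is case-insensitive regex search over the mapping table in
    order.  Unmapped names are lowercased, whitespace-normalised, returned
    verbatim and logged once each.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("empty PTM name")
    table = DEFAULT_NAME_MAP if mapping_table is None else mapping_table
    for pattern, canonical in table:
        if re.search(pattern, raw_name, flags=re.IGNORECASE):
            return canonical
    normalized = re.sub(r"\s+", " ", raw_name.strip().lower())
    if normalized not in _unmapped_seen:
        _unmapped_seen.add(normalized)
        logger.warning("unmapped PTM name %r kept verbatim", normalized)
    return normalized


@dataclass
class PTMSite:
    """A deduplicated modification locus: one (accession, position) pair
    carrying every canonical type and source that reported it."""

    accession: str
    position: int
    residue: str  # one-letter code, '?' when unknown
    types: set[str]
    sources: set[str]
    raw_names: set[str] = field(default_factory=set)

    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def is_crosstalk(self) -> bool:
        return len(self.types) >= 2


@dataclass(frozen=True)
class CrosstalkSite:
    """View of a catalog site where >=2 canonical types compete in situ."""

    site: PTMSite

    @property
    def n_types(self) -> int:
        return self.site.n_types

    def __post_init__(self) -> None:
        if self.site.n_types < 2:
            raise ValueError("crosstalk site requires >=2 types")


@dataclass
class ProteinPTMSummary:
    accession: str
    n_sites: int
    n_types: int
    n_crosstalk_sites: int
    sites_per_type: dict[str, int]


def build_catalog(
    raw_sites: Iterable,
    proteome: Mapping[str, ProteinRecord] | None = None,
    name_map: Sequence[tuple[str, str]] | None = None,
) -> list[PTMSite]:
    """Collapse raw multi-source records into the deduplicated site catalog.

    Records are grouped by (accession, position); canonical types and sources
    are unions over the group.  When a proteome is supplied, sites beyond the
    sequence end are dropped (logged) and the sequence residue overrides any
    conflicting reported residue (logged).  Accepts either
    :class:`~ptmatlas.io_integration.PTMSiteRaw` records or already-built
    :class:`PTMSite` objects, so rebuilding a catalog from its own output is
    a fixed point.
    """
    grouped: dict[tuple[str, int], PTMSite] = {}
    n_dropped = 0
    n_mismatch = 0
    for rec in raw_sites:
        if isinstance(rec, PTMSite):
            types = set(rec.types)
            sources = set(rec.sources)
            raw_names = set(rec.raw_names)
            residue = rec.residue if rec.residue != "?" else ""
        else:
            types = {canonicalize_ptm_name(rec.ptm_name_raw, name_map)}
            sources = {rec.source_db}
            raw_names = {rec.ptm_name_raw}
            residue = rec.residue
        key = (rec.accession, rec.position)
        seq_residue = ""
        if proteome is not None and rec.accession in proteome:
            seq = proteome[rec.accession].sequence
            if rec.position > len(seq):
                n_dropped += 1
                continue
            seq_residue = seq[rec.position - 1]
            if residue and residue != seq_residue:
                n_mismatch += 1
        site = grouped.get(key)
        if site is None:
            grouped[key] = PTMSite(
                accession=rec.accession,
                position=rec.position,
                residue=seq_residue or residue or "?",
                types=types,
                sources=sources,
                raw_names=raw_names,
            )
        else:
            site.types |= types
            site.sources |= sources
            site.raw_names |= raw_names
            if seq_residue:
                site.residue = seq_residue
            elif site.residue == "?" and residue:
                site.residue = residue
    if n_dropped:
        logger.info("build_catalog: dropped %d sites beyond sequence end", n_dropped)
    if n_mismatch:
        logger.info(
            "build_catalog: %d residue conflicts resolved in favour of the sequence",
            n_mismatch,
        )
    return sorted(grouped.values(), key=lambda s: (s.accession, s.position))


def find_crosstalk_sites(catalog: Iterable[PTMSite]) -> list[CrosstalkSite]:
    """Sites where at least two canonical PTM types compete for one residue."""
    return [CrosstalkSite(site) for site in catalog if site.n_types >= 2]


def crosstalk_census(
    crosstalk_sites: Iterable[CrosstalkSite],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Census of type combinations at crosstalk sites.

    Returns (combinations, histogram): the first counts sites per sorted
    type combination ('acetylation+ubiquitination'), the second counts sites
    per number of competing types.  Both totals equal the number of
    crosstalk sites.
    """
    combos: Counter[str] = Counter()
    by_n: Counter[int] = Counter()
    for cs in crosstalk_sites:
        combos["+".join(sorted(cs.site.types))] += 1
        by_n[cs.n_types] += 1
    combo_frame = pd.DataFrame(
        sorted(combos.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["combination", "n_sites"],
    )
    hist_frame = pd.DataFrame(
        sorted(by_n.items()), columns=["n_types", "n_sites"]
    )
    return combo_frame, hist_frame


def summarize_proteins(
    catalog: Iterable[PTMSite],
) -> tuple[list[ProteinPTMSummary], dict]:
    """Per-protein site statistics plus the global summary.

    The global summary reports mean sites per protein, mean distinct types
    per protein and the distribution of types-per-protein, all over proteins
    with at least one cataloged site.
    """
    per_protein: dict[str, list[PTMSite]] = defaultdict(list)
    for site in catalog:
        per_protein[site.accession].append(site)
    summaries: list[ProteinPTMSummary] = []
    for acc in sorted(per_protein):
        sites = per_protein[acc]
        types_here: set[str] = set()
        per_type: Counter[str] = Counter()
        n_cross = 0
        for s in sites:
            types_here |= s.types
            for t in s.types:
                per_type[t] += 1
            if s.is_crosstalk:
                n_cross += 1
        summaries.append(
            ProteinPTMSummary(
                accession=acc,
                n_sites=len(sites),
                n_types=len(types_here),
                n_crosstalk_sites=n_cross,
                sites_per_type=dict(per_type),
            )
        )
    n_prot = len(summaries)
    global_summary = {
        "n_proteins": n_prot,
        "n_sites": sum(s.n_sites for s in summaries),
        "mean_sites_per_protein": (
            sum(s.n_sites for s in summaries) / n_prot if n_prot else float("nan")
        ),
        "mean_types_per_protein": (
            sum(s.n_types for s in summaries) / n_prot if n_prot else float("nan")
        ),
        "types_per_protein_distribution": dict(
            Counter(s.n_types for s in summaries)
        ),
        "n_crosstalk_sites": sum(s.n_crosstalk_sites for s in summaries),
    }
    return summaries, global_summary


def catalog_to_frame(catalog: Iterable[PTMSite]) -> pd.DataFrame:
    """Tabular form of the catalog (semicolon-joined sets, sorted)."""
    rows = [
        (
            s.accession,
            s.position,
            s.residue,
            ";".join(sorted(s.types)),
            ";".join(sorted(s.sources)),
            s.n_types,
        )
        for s in catalog
    ]
    return pd.DataFrame(
        rows, columns=["accession", "position", "residue", "types", "sources", "n_types"]
    )


def frame_to_catalog(frame: pd.DataFrame) -> list[PTMSite]:
    sites = []
    for row in frame.itertuples(index=False):
        sites.append(
            PTMSite(
                accession=row.accession,
                position=int(row.position),
                residue=row.residue,
                types=set(str(row.types).split(";")),
                sources=set(str(row.sources).split(";")) if row.sources else set(),
            )
        )
    return sites
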