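"""Motif extraction, positional co-occurrence profiles, hotspot scanning and
region stitching.

The motif is the +/-7-residue window centered on a modification site (at
most 15 aa; clipped at the protein termini without pro-rating the
thresholds).  Two window census rules define the hotspots:

* *PTM hotspot*: the window around a site contains at least ``k`` (default
  5) other deduplicated PTM sites, the central site excluded.  The counting
  unit is the site (position), not the type occurrence, so a two-type
  crosstalk site counts once.
* *Crosstalk hotspot*: the window around an in-situ crosstalk site contains
  at least ``k`` (default 3) crosstalk sites, the central site *included*
  (three clustered crosstalk sites suffice); ``include_center=False`` gives
  the stricter exclusive reading.

Qualifying windows of one kind on one protein are stitched into maximal
regions by merging genuinely overlapping intervals (sharing at least one
position; merely adjacent intervals stay separate), from which sequence
coverage and the crosstalk/PTM hotspot ratio are computed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ptm_catalog import PTMSite

DEFAULT_FLANK = 7
DEFAULT_K_PTM = 5
DEFAULT_K_CROSSTALK = 3


@dataclass(frozen=True)
class Motif:
    """The clipped +/-flank window around one anchoring site."""

    accession: str
    center: int
    window_start: int
    window_end: int
    truncated_left: bool
    truncated_right: bool

    def __len__(self) -> int:
        return self.window_end - self.window_start + 1


@dataclass(frozen=True)
class HotspotRegion:
    accession: str
    start: int
    end: int
    kind: str  # "ptm" | "crosstalk"
    n_qualifying_centers: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class PositionalProfile:
    """Fractions of co-occurring sites per relative motif position.

    ``fractions[offset]`` is the share of all tallied co-occurrences found
    at that relative position; offsets run -flank..+flank, with 0 present
    only in center-inclusive mode.  Fractions sum to 1 when ``n_total > 0``.
    """

    subject: str
    include_center: bool
    offsets: tuple[int, ...]
    fractions: dict[int, float] = field(default_factory=dict)
    n_total: int = 0


@dataclass
class ProteinHotspotSummary:
    accession: str
    n_ptm_hotspot_centers: int
    n_crosstalk_hotspot_centers: int
    ptm_coverage: float
    crosstalk_coverage: float
    ratio: float | None  # crosstalk / PTM centers; None when undefined


def extract_motif(sequence_length: int, center: int, flank: int = DEFAULT_FLANK,
                  accession: str = "") -> Motif:
    """The +/-flank window around ``center``, clipped to [1, L].

    A side counts as truncated when the nominal window reaches the
    corresponding terminus (touching-boundary semantics); thresholds are
    never pro-rated for truncated windows.
    """
    if not 1 <= center <= sequence_length:
        raise ValueError(
            f"center {center} outside sequence [1, {sequence_length}]"
        )
    start = max(1, center - flank)
    end = min(sequence_length, center + flank)
    return Motif(
        accession=accession,
        center=center,
        window_start=start,
        window_end=end,
        truncated_left=center - flank <= 1,
        truncated_right=center + flank >= sequence_length,
    )


def scan_ptm_hotspots(
    protein_sites: Iterable[int],
    sequence_length: int,
    k: int = DEFAULT_K_PTM,
    flank: int = DEFAULT_FLANK,
    accession: str = "",
) -> list[Motif]:
    """Windows qualifying as PTM hotspots on one protein.

    ``protein_sites`` is the deduplicated position set.  A window centered
    on site c qualifies when at least ``k`` other sites lie within the
    clipped window (equivalently within distance ``flank``).
    """
    positions = np.asarray(sorted(set(protein_sites)), dtype=np.int64)
    out: list[Motif] = []
    for c in positions:
        n_near = int(np.count_nonzero(np.abs(positions - c) <= flank)) - 1
        if n_near >= k:
            out.append(extract_motif(sequence_length, int(c), flank, accession))
    return out


def scan_crosstalk_hotspots(
    protein_crosstalk_sites: Iterable[int],
    sequence_length: int,
    k: int = DEFAULT_K_CROSSTALK,
    flank: int = DEFAULT_FLANK,
    accession: str = "",
    include_center: bool = True,
) -> list[Motif]:
    """Windows qualifying as crosstalk hotspots on one protein.

    Positions must be restricted to in-situ crosstalk sites (>=2 competing
    types).  The central site counts toward ``k`` unless
    ``include_center=False``.
    """
    positions = np.asarray(sorted(set(protein_crosstalk_sites)), dtype=np.int64)
    out: list[Motif] = []
    for c in positions:
        n_in = int(np.count_nonzero(np.abs(positions - c) <= flank))
        if not include_center:
            n_in -= 1
        if n_in >= k:
            out.append(extract_motif(sequence_length, int(c), flank, accession))
    return out


def stitch_regions(qualifying_motifs: Sequence[Motif], kind: str) -> list[HotspotRegion]:
    """Merge overlapping qualifying windows of one kind on one protein into
    maximal regions.  Intervals merge only when they share at least one
    position; end-to-start adjacency is not merged."""
    if not qualifying_motifs:
        return []
    accessions = {m.accession for m in qualifying_motifs}
    if len(accessions) > 1:
        raise ValueError(f"motifs from multiple proteins: {sorted(accessions)}")
    ordered = sorted(qualifying_motifs, key=lambda m: (m.window_start, m.window_end))
    regions: list[HotspotRegion] = []
    cur_start, cur_end, n = ordered[0].window_start, ordered[0].window_end, 1
    acc = ordered[0].accession
    for m in ordered[1:]:
        if m.window_start <= cur_end:  # genuine overlap
            cur_end = max(cur_end, m.window_end)
            n += 1
        else:
            regions.append(HotspotRegion(acc, cur_start, cur_end, kind, n))
            cur_start, cur_end, n = m.window_start, m.window_end, 1
    regions.append(HotspotRegion(acc, cur_start, cur_end, kind, n))
    return regions


def coverage(regions: Sequence[HotspotRegion], sequence_length: int) -> float:
    """Fraction of the sequence inside stitched regions: sum of region
    lengths / L.  Overlapping input regions violate the stitching contract
    and raise."""
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    ordered = sorted(regions, key=lambda r: r.start)
    prev_end = 0
    total = 0
    for r in ordered:
        if r.start <= prev_end:
            raise ValueError("overlapping regions passed to coverage()")
        total += len(r)
        prev_end = r.end
    return total / sequence_length


def _anchor_matches(site: PTMSite, subject: frozenset[str], exact: bool) -> bool:
    return site.types == subject if exact else subject <= site.types


def positional_profile(
    catalog: Iterable[PTMSite],
    subject: str | Iterable[str],
    include_center: bool = False,
    flank: int = DEFAULT_FLANK,
    exact_combination: bool = True,
    co_type: str | None = None,
) -> PositionalProfile:
    """Positional co-occurrence profile around anchors of one PTM subject.

    ``subject`` is a canonical type or a type combination; an anchor is a
    cataloged site whose type set equals the subject (or contains it when
    ``exact_combination=False``).  For every anchor, sites at each relative
    offset within +/-flank are tallied - any cataloged site by default, or
    only sites carrying ``co_type`` when given.  In center-exclusive mode
    (the default) offset 0 is skipped; in center-inclusive mode the anchor
    itself is tallied at offset 0 under the same co-type criterion.
    Fractions are tallies normalised by the grand total.
    """
    if isinstance(subject, str):
        subject_set = frozenset({subject})
        label = subject
    else:
        subject_set = frozenset(subject)
        label = "+".join(sorted(subject_set))
    offsets = tuple(
        d for d in range(-flank, flank + 1) if include_center or d != 0
    )
    by_protein: dict[str, dict[int, PTMSite]] = defaultdict(dict)
    for site in catalog:
        by_protein[site.accession][site.position] = site
    tally = {d: 0 for d in offsets}
    for acc, sites in by_protein.items():
        for pos, site in sites.items():
            if not _anchor_matches(site, subject_set, exact_combination):
                continue
            for d in offsets:
                other = sites.get(pos + d)
                if other is None:
                    continue
                if co_type is not None and co_type not in other.types:
                    continue
                tally[d] += 1
    n_total = sum(tally.values())
    fractions = {
        d: (tally[d] / n_total if n_total else 0.0) for d in offsets
    }
    return PositionalProfile(
        subject=label,
        include_center=include_center,
        offsets=offsets,
        fractions=fractions,
        n_total=n_total,
    )


def scan_protein(
    sites: Sequence[PTMSite],
    sequence_length: int,
    k_ptm: int = DEFAULT_K_PTM,
    k_crosstalk: int = DEFAULT_K_CROSSTALK,
    flank: int = DEFAULT_FLANK,
    crosstalk_include_center: bool = True,
) -> dict:
    """Run both scans and stitching for one protein's cataloged sites."""
    if not sites:
        return {
            "ptm_motifs": [], "crosstalk_motifs": [],
            "ptm_regions": [], "crosstalk_regions": [],
        }
    acc = sites[0].accession
    positions = [s.position for s in sites]
    ct_positions = [s.position for s in sites if s.is_crosstalk]
    ptm_motifs = scan_ptm_hotspots(positions, sequence_length, k_ptm, flank, acc)
    ct_motifs = scan_crosstalk_hotspots(
        ct_positions, sequence_length, k_crosstalk, flank, acc,
        include_center=crosstalk_include_center,
    )
    return {
        "ptm_motifs": ptm_motifs,
        "crosstalk_motifs": ct_motifs,
        "ptm_regions": stitch_regions(ptm_motifs, "ptm"),
        "crosstalk_regions": stitch_regions(ct_motifs, "crosstalk"),
    }


def hotspot_summary(
    per_protein: Mapping[str, dict],
    sequence_lengths: Mapping[str, int],
    categories: Mapping[str, str] | None = None,
) -> tuple[list[ProteinHotspotSummary], dict]:
    """Per-protein summaries plus the cohort tables.

    ``per_protein`` maps accession to the output of :func:`scan_protein`.
    Cohorts: proteins with >=1 hotspot of each kind, with both, and with
    crosstalk hotspots only (possible because a protein may lack a PTM
    hotspot yet contain a crosstalk one); when disease ``categories`` are
    supplied each cohort is also split by category.
    """
    summaries: list[ProteinHotspotSummary] = []
    cohorts = {"ptm": set(), "crosstalk": set()}
    for acc in sorted(per_protein):
        res = per_protein[acc]
        L = sequence_lengths[acc]
        n_ptm = len(res["ptm_motifs"])
        n_ct = len(res["crosstalk_motifs"])
        summaries.append(
            ProteinHotspotSummary(
                accession=acc,
                n_ptm_hotspot_centers=n_ptm,
                n_crosstalk_hotspot_centers=n_ct,
                ptm_coverage=coverage(res["ptm_regions"], L),
                crosstalk_coverage=coverage(res["crosstalk_regions"], L),
                ratio=(n_ct / n_ptm) if n_ptm else None,
            )
        )
        if n_ptm:
            cohorts["ptm"].add(acc)
        if n_ct:
            cohorts["crosstalk"].add(acc)
    both = cohorts["ptm"] & cohorts["crosstalk"]
    tables = {
        "proteins_with_ptm_hotspots": cohorts["ptm"],
        "proteins_with_crosstalk_hotspots": cohorts["crosstalk"],
        "proteins_with_both": both,
        "proteins_crosstalk_only": cohorts["crosstalk"] - cohorts["ptm"],
        "proteins_ptm_only": cohorts["ptm"] - cohorts["crosstalk"],
    }
    if categories is not None:
        split = {}
        for name, accs in tables.items():
            counts: dict[str, int] = {}
            for acc in accs:
                cat = categories.get(acc, "ND")
                counts[cat] = counts.get(cat, 0) + 1
            split[name] = counts
        tables["disease_split"] = split
    return summaries, tables


def profiles_to_frame(profiles: Iterable[PositionalProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        mode = "include_center" if p.include_center else "exclude_center"
        for d in p.offsets:
            rows.append((p.subject, mode, d, p.fractions[d], p.n_total))
    return pd.DataFrame(rows, columns=["subject", "mode", "offset", "fraction", "n_total"])
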