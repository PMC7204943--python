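"""Structural-category assignment of PTM sites from per-residue disorder tracks.

A disorder track labels every residue of a protein as ordered (O),
disordered-binding (DB, a molecular recognition feature) or disordered
non-binding (DN).  The predictors producing such tracks (DISOPRED3-class
tools) are external to this package: tracks are an input format, not a
computation.

A modification site inherits the label of its residue.  Per-type fraction
tables use *sites* as the unit - for a type t and category c,
fraction(t, c) = sites of t labelled c / sites of t with a known label -
so the three fractions per type sum to one.  Sites on proteins without a
track are labelled ``unknown`` and excluded from the fractions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_integration import DISORDER_LABELS
from .ptm_catalog import CrosstalkSite, PTMSite

logger = logging.getLogger("ptmatlas.disorder")

UNKNOWN = "unknown"


@dataclass
class DisorderTrack:
    accession: str
    labels: list[str]  # per-residue, over {O, DB, DN}
    predictor_name: str = "external"

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(DISORDER_LABELS)
        if bad:
            raise ValueError(f"track for {self.accession}: unknown labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


def tracks_from_labels(
    labels: Mapping[str, list[str]],
    predictor_name: str = "external",
    proteome: Mapping | None = None,
) -> dict[str, DisorderTrack]:
    """Build validated tracks from a reader's accession -> labels mapping.

    When a proteome is supplied, a track whose length differs from the
    sequence raises an error naming the accession.
    """
    tracks: dict[str, DisorderTrack] = {}
    for acc, lab in labels.items():
        if proteome is not None and acc in proteome:
            if len(lab) != len(proteome[acc].sequence):
                raise ValueError(
                    f"track/sequence length mismatch for {acc}: "
                    f"{len(lab)} labels vs {len(proteome[acc].sequence)} residues"
                )
        tracks[acc] = DisorderTrack(acc, list(lab), predictor_name)
    return tracks


def site_category(site: PTMSite, tracks: Mapping[str, DisorderTrack]) -> str:
    track = tracks.get(site.accession)
    if track is None:
        return UNKNOWN
    if site.position > len(track):
        raise ValueError(
            f"site {site.accession}:{site.position} beyond track length {len(track)}"
        )
    return track.labels[site.position - 1]


def assign_structural_category(
    catalog: Iterable[PTMSite],
    tracks: Mapping[str, DisorderTrack],
) -> tuple[dict[tuple[str, int], str], pd.DataFrame]:
    """Label every cataloged site and tabulate per-type category fractions.

    Returns (site_labels, fractions): ``site_labels`` maps
    (accession, position) to O/DB/DN/unknown; ``fractions`` has one row per
    canonical type with counts and fractions per category (fractions over
    sites with a known label; they sum to 1 per type).
    """
    site_labels: dict[tuple[str, int], str] = {}
    counts: dict[str, Counter] = {}
    n_unknown = 0
    for site in catalog:
        cat = site_category(site, tracks)
        site_labels[(site.accession, site.position)] = cat
        if cat == UNKNOWN:
            n_unknown += 1
            continue
        for t in site.types:
            counts.setdefault(t, Counter())[cat] += 1
    if n_unknown:
        logger.info("%d sites on proteins without tracks labelled unknown", n_unknown)
    rows = []
    for t in sorted(counts):
        c = counts[t]
        total = sum(c.values())
        row = {"type": t, "n_sites": total}
        for cat in DISORDER_LABELS:
            row[f"n_{cat}"] = c.get(cat, 0)
            row[f"frac_{cat}"] = c.get(cat, 0) / total if total else float("nan")
        rows.append(row)
    fractions = pd.DataFrame(
        rows,
        columns=["type", "n_sites"]
        + [f"n_{c}" for c in DISORDER_LABELS]
        + [f"frac_{c}" for c in DISORDER_LABELS],
    )
    return site_labels, fractions


def crosstalk_disorder_summary(
    crosstalk_sites: Iterable[CrosstalkSite],
    tracks: Mapping[str, DisorderTrack],
) -> pd.DataFrame:
    """Category fractions restricted to in-situ crosstalk sites (one row)."""
    counter: Counter = Counter()
    for cs in crosstalk_sites:
        cat = site_category(cs.site, tracks)
        if cat != UNKNOWN:
            counter[cat] += 1
    total = sum(counter.values())
    if total == 0:
        logger.warning("no crosstalk sites with known structural category")
        return pd.DataFrame(
            columns=["n_sites"]
            + [f"n_{c}" for c in DISORDER_LABELS]
            + [f"frac_{c}" for c in DISORDER_LABELS]
        )
    row = {"n_sites": total}
    for cat in DISORDER_LABELS:
        row[f"n_{cat}"] = counter.get(cat, 0)
        row[f"frac_{cat}"] = counter.get(cat, 0) / total
    return pd.DataFrame([row])
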