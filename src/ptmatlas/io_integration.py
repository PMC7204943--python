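"""Readers and writers for the external file dialects consumed by the pipeline.

Every tabular format is UTF-8, tab-separated, with a header row; lines
beginning with ``#`` are comments.  Positions are 1-based and inclusive
throughout the package, following protein-database convention.  The readers
normalise each dialect into the shared domain records defined here; all
downstream logic operates on those records, never on raw files.

Dropped rows (wrong organism, below-threshold conservation, unmappable gene
symbols) are counted and reported through the ``ptmatlas.io`` logger so that
``len(records) + dropped == rows read`` always holds.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("ptmatlas.io")

PTM_SOURCES = ("dbPTM", "PSP", "neXtProt", "other")
PPI_SOURCES = ("APID", "BioGRID", "HIPPIE", "STRING", "IntAct", "other")


class ParseError(ValueError):
    """A malformed input file (bad row, bad FASTA structure, bad notation)."""


class ConfigError(ValueError):
    """An invalid configuration value (unknown dialect, too few sources)."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence entry.

    ``sequence`` is uppercase; the 20 standard letters plus X/U/B/Z are
    tolerated.  ``gene_symbol`` may be empty when the FASTA header carries
    none.
    """

    accession: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.accession}")


@dataclass(frozen=True)
class PTMSiteRaw:
    """One as-read modification record, before canonicalisation/dedup."""

    accession: str
    position: int
    residue: str  # one-letter code, '' if the dialect omits it
    ptm_name_raw: str
    source_db: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class InteractionEdgeRaw:
    accession_a: str
    accession_b: str
    source_db: str

    def __post_init__(self) -> None:
        if not self.accession_a or not self.accession_b:
            raise ValueError("both accessions must be non-empty")


@dataclass(frozen=True)
class DiseaseAssociationRaw:
    gene_or_accession: str
    disease_name: str

    def __post_init__(self) -> None:
        if not self.gene_or_accession or not self.disease_name:
            raise ValueError("both fields must be non-empty")


@dataclass(frozen=True)
class CisCrosstalkRecord:
    """A coevolution-derived crosstalk pair between two positions of one protein."""

    accession: str
    position_1: int
    position_2: int
    conservation_score: float

    def __post_init__(self) -> None:
        if self.position_1 == self.position_2:
            raise ValueError("positions of a cis pair must differ")
        if self.position_1 < 1 or self.position_2 < 1:
            raise ValueError("positions must be >= 1")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_GENE_RE = re.compile(r"\bGN=(\S+)")


def read_fasta(path: str | Path, accession_regex: str | None = None) -> list[ProteinRecord]:
    """Read a FASTA proteome into :class:`ProteinRecord` objects.

    The accession is the header's first whitespace-delimited token; when
    ``accession_regex`` is given (e.g. ``r"sp\\|([^|]+)\\|"`` for UniProt
    pipe-delimited headers) its first capture group is used instead.
    Sequences are uppercased.  A duplicate accession raises :class:`ParseError`.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: sequence data before first FASTA header"
                    )
                break
    pattern = re.compile(accession_regex) if accession_regex else None
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        accession = rec.id
        if pattern is not None:
            m = pattern.search(header)
            if m:
                accession = m.group(1)
        if accession in seen:
            raise ParseError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        gm = _GENE_RE.search(header)
        records.append(
            ProteinRecord(accession, gm.group(1) if gm else "", str(rec.seq).upper())
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.accession
            if rec.gene_symbol:
                header += f" GN={rec.gene_symbol}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# generic TSV plumbing
# ---------------------------------------------------------------------------

def _iter_rows(path: str | Path):
    """Yield (lineno, fields) for non-comment, non-blank lines of a TSV."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.rstrip("\n").split("\t")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read any pipeline TSV (header row, '#' comments) into a DataFrame."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame in the pipeline's canonical TSV form."""
    frame.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def _parse_int(text: str, path, lineno: int, what: str = "position") -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-integer {what} {text!r}") from None


# ---------------------------------------------------------------------------
# PTM site tables
# ---------------------------------------------------------------------------

# Dialect adapters.  ``generic`` is the package's own interchange format; the
# named adapters cover simplified flat-file layouts of the upstream databases
# (the historical column layouts of each release are not reproduced
# bit-for-bit).
PTM_DIALECTS = ("generic", "dbptm", "psp", "nextprot")

# PhosphoSitePlus-style MOD_RSD suffix codes
_PSP_SUFFIX = {
    "p": "Phosphorylation",
    "ac": "Acetylation",
    "ub": "Ubiquitination",
    "sm": "Sumoylation",
    "me": "Methylation",
    "m1": "Methylation",
    "m2": "Dimethylation",
    "m3": "Trimethylation",
    "gl": "O-GlcNAc",
    "ga": "O-GalNAc",
    "sc": "Succinylation",
    "ma": "Malonylation",
}


def read_ptm_table(
    path: str | Path,
    dialect: str = "generic",
    organism: str = "human",
) -> list[PTMSiteRaw]:
    """Read one PTM site table in the given dialect.

    ``generic``: header TSV with columns accession, position, residue,
    ptm_name, source and an optional organism column.  ``dbptm``: headerless
    gene/accession/position/type rows.  ``psp``: header TSV with ACC_ID,
    MOD_RSD (``K382-ac`` style) and ORGANISM.  ``nextprot``: header TSV with
    accession, position, residue, ptm_name.

    Rows for organisms other than ``organism`` (case-insensitive, when the
    dialect carries an organism column) are dropped; the drop count is logged.
    """
    if dialect not in PTM_DIALECTS:
        raise ConfigError(f"unknown PTM dialect {dialect!r}; expected one of {PTM_DIALECTS}")
    path = Path(path)
    records: list[PTMSiteRaw] = []
    dropped = 0
    rows = _iter_rows(path)
    if dialect == "generic":
        header = None
        for lineno, fields in rows:
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                for required in ("accession", "position", "ptm_name"):
                    if required not in header:
                        raise ParseError(f"{path}: missing column {required!r}")
                continue
            org_idx = header.get("organism")
            if org_idx is not None and fields[org_idx].lower() != organism.lower():
                dropped += 1
                continue
            records.append(
                PTMSiteRaw(
                    accession=fields[header["accession"]],
                    position=_parse_int(fields[header["position"]], path, lineno),
                    residue=fields[header["residue"]] if "residue" in header else "",
                    ptm_name_raw=fields[header["ptm_name"]],
                    source_db=fields[header["source"]] if "source" in header else "other",
                )
            )
    elif dialect == "dbptm":
        for lineno, fields in rows:
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 columns")
            records.append(
                PTMSiteRaw(
                    accession=fields[1],
                    position=_parse_int(fields[2], path, lineno),
                    residue="",
                    ptm_name_raw=fields[3],
                    source_db="dbPTM",
                )
            )
    elif dialect == "psp":
        header = None
        mod_re = re.compile(r"^([A-Za-z])(\d+)-(\w+)$")
        for lineno, fields in rows:
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                continue
            org_idx = header.get("ORGANISM")
            if org_idx is not None and fields[org_idx].lower() != organism.lower():
                dropped += 1
                continue
            mod = fields[header["MOD_RSD"]]
            m = mod_re.match(mod)
            if not m:
                raise ParseError(f"{path}: line {lineno}: cannot parse MOD_RSD {mod!r}")
            suffix = m.group(3).lower()
            records.append(
                PTMSiteRaw(
                    accession=fields[header["ACC_ID"]],
                    position=_parse_int(m.group(2), path, lineno),
                    residue=m.group(1).upper(),
                    ptm_name_raw=_PSP_SUFFIX.get(suffix, suffix),
                    source_db="PSP",
                )
            )
    else:  # nextprot
        header = None
        for lineno, fields in rows:
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                continue
            records.append(
                PTMSiteRaw(
                    accession=fields[header["accession"]],
                    position=_parse_int(fields[header["position"]], path, lineno),
                    residue=fields[header["residue"]] if "residue" in header else "",
                    ptm_name_raw=fields[header["ptm_name"]],
                    source_db="neXtProt",
                )
            )
    if dropped:
        logger.info("read_ptm_table(%s): dropped %d non-%s rows", path, dropped, organism)
    return records


def write_ptm_table(records: Iterable[PTMSiteRaw], path: str | Path) -> None:
    """Write PTM records in the generic dialect (round-trips with the reader)."""
    frame = pd.DataFrame(
        [
            (r.accession, r.position, r.residue, r.ptm_name_raw, r.source_db)
            for r in records
        ],
        columns=["accession", "position", "residue", "ptm_name", "source"],
    )
    write_table(frame, path)


# ---------------------------------------------------------------------------
# interaction edges
# ---------------------------------------------------------------------------

def read_interaction_table(path: str | Path, source_db: str) -> list[InteractionEdgeRaw]:
    """Read a two-column (plus optional extras) TSV of interactor pairs.

    Pair order is preserved as read; normalisation to undirected edges is the
    network module's job (so self-loops pass through here by contract).
    """
    path = Path(path)
    edges: list[InteractionEdgeRaw] = []
    for lineno, fields in _iter_rows(path):
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected >=2 columns")
        if fields[0] == "accession_a":  # optional header row
            continue
        edges.append(InteractionEdgeRaw(fields[0], fields[1], source_db))
    if not edges:
        logger.warning("read_interaction_table(%s): empty edge list", path)
    return edges


def write_interaction_table(edges: Iterable[InteractionEdgeRaw], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(e.accession_a, e.accession_b) for e in edges],
        columns=["accession_a", "accession_b"],
    )
    write_table(frame, path)


# ---------------------------------------------------------------------------
# disease associations and gene-symbol reconciliation
# ---------------------------------------------------------------------------

def read_disease_table(path: str | Path) -> list[DiseaseAssociationRaw]:
    """Read a header TSV with columns gene_or_accession, disease_name."""
    path = Path(path)
    out: list[DiseaseAssociationRaw] = []
    header = None
    for lineno, fields in _iter_rows(path):
        if header is None:
            header = {name: i for i, name in enumerate(fields)}
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        out.append(DiseaseAssociationRaw(fields[0], fields[1]))
    return out


def read_gene_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column gene_symbol -> accession mapping table."""
    mapping: dict[str, str] = {}
    header_seen = False
    for lineno, fields in _iter_rows(path):
        if not header_seen:
            header_seen = True
            if fields[0] in ("gene_symbol", "symbol"):
                continue
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        mapping[fields[0]] = fields[1]
    return mapping


def apply_gene_mapping(
    associations: Sequence[DiseaseAssociationRaw],
    mapping: Mapping[str, str] | None,
    known_accessions: set[str] | None = None,
) -> list[DiseaseAssociationRaw]:
    """Re-key gene-symbol associations onto accessions.

    Keys already present in ``known_accessions`` pass through unchanged;
    other keys are looked up in ``mapping``.  Unmappable symbols are dropped
    and the count logged.
    """
    mapping = mapping or {}
    out: list[DiseaseAssociationRaw] = []
    dropped = 0
    for assoc in associations:
        key = assoc.gene_or_accession
        if known_accessions is not None and key in known_accessions:
            out.append(assoc)
        elif key in mapping:
            out.append(DiseaseAssociationRaw(mapping[key], assoc.disease_name))
        elif known_accessions is None:
            out.append(assoc)
        else:
            dropped += 1
    if dropped:
        logger.info("apply_gene_mapping: dropped %d unmappable symbols", dropped)
    return out


# ---------------------------------------------------------------------------
# cis crosstalk
# ---------------------------------------------------------------------------

def read_cis_crosstalk(path: str | Path, min_score: float = 80.0) -> list[CisCrosstalkRecord]:
    """Read a cis-crosstalk pair table, keeping records with residue
    conservation score >= ``min_score`` (default 80)."""
    path = Path(path)
    out: list[CisCrosstalkRecord] = []
    dropped = 0
    header = None
    for lineno, fields in _iter_rows(path):
        if header is None:
            header = {name: i for i, name in enumerate(fields)}
            continue
        score = float(fields[header["conservation_score"]])
        if score < min_score:
            dropped += 1
            continue
        out.append(
            CisCrosstalkRecord(
                accession=fields[header["accession"]],
                position_1=_parse_int(fields[header["position_1"]], path, lineno),
                position_2=_parse_int(fields[header["position_2"]], path, lineno),
                conservation_score=score,
            )
        )
    if dropped:
        logger.info("read_cis_crosstalk(%s): dropped %d records below score %s",
                    path, dropped, min_score)
    return out


def write_cis_crosstalk(records: Iterable[CisCrosstalkRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.accession, r.position_1, r.position_2, r.conservation_score) for r in records],
        columns=["accession", "position_1", "position_2", "conservation_score"],
    )
    write_table(frame, path)


# ---------------------------------------------------------------------------
# disorder tracks
# ---------------------------------------------------------------------------

DISORDER_LABELS = ("O", "DB", "DN")
_COMPACT_CODE = {"O": "O", "B": "DB", "N": "DN"}
_COMPACT_REV = {"O": "O", "DB": "B", "DN": "N"}


def read_disorder_labels(path: str | Path) -> dict[str, list[str]]:
    """Read per-residue disorder labels, long or compact form.

    Long form: header TSV (accession, position, label) with one row per
    residue.  Compact form: header TSV (accession, track) where ``track`` is
    a per-residue string over {O, B, N} = ordered / disordered-binding /
    disordered non-binding.  Returns accession -> label list over
    {"O", "DB", "DN"}.
    """
    path = Path(path)
    header = None
    long_form = None
    per_protein: dict[str, dict[int, str]] = {}
    compact: dict[str, list[str]] = {}
    for lineno, fields in _iter_rows(path):
        if header is None:
            header = {name: i for i, name in enumerate(fields)}
            long_form = "position" in header
            if long_form and "label" not in header:
                raise ParseError(f"{path}: long-form track needs a 'label' column")
            if not long_form and "track" not in header:
                raise ParseError(f"{path}: compact track needs a 'track' column")
            continue
        acc = fields[header["accession"]]
        if long_form:
            pos = _parse_int(fields[header["position"]], path, lineno)
            label = fields[header["label"]]
            if label not in DISORDER_LABELS:
                raise ParseError(f"{path}: line {lineno}: unknown label {label!r}")
            per_protein.setdefault(acc, {})[pos] = label
        else:
            track = fields[header["track"]]
            try:
                compact[acc] = [_COMPACT_CODE[c] for c in track]
            except KeyError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: unknown track code {exc.args[0]!r}"
                ) from None
    if long_form:
        out: dict[str, list[str]] = {}
        for acc, posmap in per_protein.items():
            n = max(posmap)
            if set(posmap) != set(range(1, n + 1)):
                raise ParseError(f"{path}: track for {acc} has gaps")
            out[acc] = [posmap[i] for i in range(1, n + 1)]
        return out
    return compact


def write_disorder_labels(labels: Mapping[str, Sequence[str]], path: str | Path) -> None:
    """Write tracks in the compact form (one row per protein)."""
    frame = pd.DataFrame(
        [(acc, "".join(_COMPACT_REV[c] for c in track)) for acc, track in labels.items()],
        columns=["accession", "track"],
    )
    write_table(frame, path)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the single YAML run configuration naming every input path,
    dialect and threshold."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg
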