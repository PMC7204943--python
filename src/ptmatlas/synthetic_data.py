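"""Fully parameterised synthetic study bundle with planted ground truth.

The generator emulates the statistical shape of the inputs the pipeline
consumes - a proteome, multi-source PTM site tables, multi-source PPI edge
lists, disease associations, disorder tracks, variant tables and
cis-crosstalk records - with every interesting feature *planted* so each
pipeline stage can be scored against known truth:

* per-type site densities (Poisson counts per protein, positions uniform
  over residues permitted for the type, no two types on one background
  position so in-situ crosstalk is exactly what was planted);
* a Bernoulli second competing type per site (``crosstalk_fraction``);
* dense site clusters on designated hotspot proteins;
* multi-database source overlap for both PTM and PPI records, plus a
  fraction of single-source proteins that must fail the two-database
  consensus rule;
* degree-inflated hub proteins;
* a CVD / OD / ND category per protein realised as disease associations;
* alternating geometric ordered/disordered segments with a target ordered
  fraction;
* disease variants placed at a modification site with probability ``p0``
  and elsewhere inside the +/-7 motif otherwise.

With a fixed seed the emitted bundle is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import disease_classify
from .io_integration import (
    CisCrosstalkRecord,
    InteractionEdgeRaw,
    ProteinRecord,
    PTMSiteRaw,
    write_cis_crosstalk,
    write_disorder_labels,
    write_fasta,
    write_interaction_table,
    write_ptm_table,
    write_table,
)
from .variant_map import VariantRecord, write_variants

logger = logging.getLogger("ptmatlas.synthetic")

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

# Approximate human proteome amino-acid composition
DEFAULT_AA_WEIGHTS: dict[str, float] = {
    "A": 7.0, "C": 2.3, "D": 4.7, "E": 7.1, "F": 3.7, "G": 6.6, "H": 2.6,
    "I": 4.3, "K": 5.7, "L": 9.9, "M": 2.1, "N": 3.6, "P": 6.3, "Q": 4.8,
    "R": 5.6, "S": 8.3, "T": 5.3, "V": 6.0, "W": 1.2, "Y": 2.7,
}

# Residues each modification type may occupy.  Every letter reachable by a
# type offers at least two types, so a planted second competing type always
# exists.
DEFAULT_RESIDUE_MAP: dict[str, str] = {
    "phosphorylation": "STY",
    "o-glycosylation": "ST",
    "sulfation": "Y",
    "acetylation": "K",
    "ubiquitination": "K",
    "methylation": "K",
    "sumoylation": "K",
    "succinylation": "K",
    "malonylation": "K",
    "glutarylation": "K",
    "butyrylation": "K",
    "crotonylation": "K",
    "n-glycosylation": "N",
    "deamidation": "N",
    "s-nitrosylation": "C",
    "glutathionylation": "C",
}

# Default per-type site densities (sites per 100 aa).  Chosen so that a
# random background +/-7 window essentially never reaches the hotspot
# thresholds (false-window probability below 1e-3 for both hotspot kinds),
# which makes planted clusters cleanly separable from background.
DEFAULT_SITE_DENSITY: dict[str, float] = {
    "phosphorylation": 2.0,
    "ubiquitination": 1.0,
    "acetylation": 0.8,
    "methylation": 0.3,
    "sumoylation": 0.15,
    "succinylation": 0.10,
    "malonylation": 0.08,
    "glutarylation": 0.04,
    "butyrylation": 0.04,
    "crotonylation": 0.04,
    "n-glycosylation": 0.15,
    "o-glycosylation": 0.10,
    "s-nitrosylation": 0.10,
    "glutathionylation": 0.06,
    "sulfation": 0.04,
    "deamidation": 0.04,
}

# Verbatim spellings emitted into the raw tables, exercising canonicalisation
RAW_NAME_BY_TYPE: dict[str, dict[str, str] | str] = {
    "phosphorylation": {"S": "Phosphoserine", "T": "Phosphothreonine", "Y": "Phosphotyrosine"},
    "acetylation": "N6-acetyllysine",
    "ubiquitination": "Ubiquitination",
    "methylation": "N6-methyllysine",
    "sumoylation": "Sumoylation",
    "succinylation": "N6-succinyllysine",
    "malonylation": "N6-malonyllysine",
    "glutarylation": "N6-glutaryllysine",
    "butyrylation": "N6-butyryllysine",
    "crotonylation": "N6-crotonyllysine",
    "n-glycosylation": "N-linked Glycosylation",
    "o-glycosylation": "O-linked Glycosylation",
    "s-nitrosylation": "S-nitrosocysteine",
    "glutathionylation": "S-glutathionyl cysteine",
    "sulfation": "Sulfotyrosine",
    "deamidation": "Deamidated asparagine",
}

OTHER_DISEASES = (
    "breast carcinoma", "alzheimer disease", "parkinson disease",
    "type 2 diabetes mellitus", "colorectal cancer", "hepatocellular carcinoma",
    "rheumatoid arthritis", "asthma", "chronic kidney disease", "melanoma",
    "prostate cancer", "schizophrenia", "epilepsy", "osteoporosis",
    "ulcerative colitis", "amyotrophic lateral sclerosis", "cystic fibrosis",
    "psoriasis", "multiple sclerosis", "gastric cancer",
)

PPI_SOURCE_NAMES = ("APID", "BioGRID", "HIPPIE", "STRING", "IntAct")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    n_proteins: int = 200
    n_seeds: int = 7
    length_mean: float = 450.0
    length_sigma: float = 0.35
    length_min: int = 150
    length_max: int = 1500
    aa_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_WEIGHTS))
    site_density: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_DENSITY))
    residue_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RESIDUE_MAP))
    crosstalk_fraction: float = 0.05
    flank: int = 7
    n_hotspot_proteins: int = 10
    n_crosstalk_hotspot_proteins: int = 5
    cluster_sites: int = 7
    cluster_span: int = 8
    crosstalk_cluster_sites: int = 4
    ptm_source_probs: dict[str, float] = field(
        default_factory=lambda: {"dbPTM": 0.8, "PSP": 0.6, "neXtProt": 0.35}
    )
    ppi_source_probs: dict[str, float] = field(
        default_factory=lambda: {
            "APID": 0.7, "BioGRID": 0.7, "HIPPIE": 0.5, "STRING": 0.5, "IntAct": 0.4
        }
    )
    single_source_fraction: float = 0.10
    interactor_edge_rate: float = 0.8
    n_planted_hubs: int = 10
    hub_extra_degree: int = 30
    cvd_prob: float = 0.40
    od_prob: float = 0.45
    other_disease_rate: float = 1.0
    ordered_fraction: float = 0.65
    mean_ordered_segment: float = 30.0
    db_fraction: float = 0.4
    variants_per_protein: float = 6.0
    variant_class_probs: dict[str, float] = field(
        default_factory=lambda: {"disease": 0.45, "polymorphism": 0.35, "unclassified": 0.20}
    )
    at_site_p0: float = 0.30
    cis_per_protein: float = 1.0
    cis_score_low: float = 50.0
    cis_score_high: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.cluster_sites > self.cluster_span:
            raise ValueError(
                f"cluster of {self.cluster_sites} sites cannot fit a "
                f"{self.cluster_span}-residue span"
            )
        if self.crosstalk_cluster_sites > self.cluster_span:
            raise ValueError("crosstalk cluster exceeds its span")
        if self.cluster_span + 2 * self.flank >= self.length_min:
            raise ValueError("cluster window does not fit the shortest protein")
        n_planted = self.n_hotspot_proteins + self.n_crosstalk_hotspot_proteins
        if n_planted > self.n_proteins:
            raise ValueError("more planted hotspot proteins than proteins")
        for name, dens in self.site_density.items():
            if dens < 0:
                raise ValueError(f"negative density for {name}")
            if name not in self.residue_map:
                raise ValueError(f"no residue constraint for type {name}")
        for p in (self.crosstalk_fraction, self.single_source_fraction,
                  self.cvd_prob, self.od_prob, self.ordered_fraction,
                  self.db_fraction, self.at_site_p0):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.cvd_prob + self.od_prob > 1.0:
            raise ValueError("cvd_prob + od_prob exceeds 1")


def default_config(**overrides) -> GeneratorConfig:
    return dataclasses.replace(GeneratorConfig(), **overrides)


def compendium_config(**overrides) -> GeneratorConfig:
    """A denser preset whose summary shapes (phosphorylation >> ubiquitination
    >> acetylation; several types per protein; tens of sites per protein)
    qualitatively echo curated human PTM compendia.  Clearly synthetic: the
    background is dense enough that hotspot windows also arise by chance,
    so it is not suitable for planted-hotspot scoring."""
    density = {
        "phosphorylation": 10.0, "ubiquitination": 3.0, "acetylation": 2.0,
        "methylation": 0.6, "sumoylation": 0.25, "succinylation": 0.2,
        "malonylation": 0.12, "glutarylation": 0.05, "butyrylation": 0.05,
        "crotonylation": 0.05, "n-glycosylation": 0.2, "o-glycosylation": 0.15,
        "s-nitrosylation": 0.1, "glutathionylation": 0.06, "sulfation": 0.05,
        "deamidation": 0.05,
    }
    weights = dict(DEFAULT_AA_WEIGHTS)
    weights.update({"K": 9.0, "S": 10.0, "T": 6.5, "Y": 3.5})
    cfg = GeneratorConfig(
        site_density=density,
        aa_weights=weights,
        crosstalk_fraction=0.12,
    )
    return dataclasses.replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Everything planted, for scoring pipeline recovery."""

    categories: dict[str, str]
    planted_ptm_hotspots: list[tuple[str, int, int]]
    planted_crosstalk_hotspots: list[tuple[str, int, int]]
    planted_hubs: list[str]
    consensus_accessions: list[str]
    single_source_accessions: list[str]
    sites: dict[str, list[tuple[int, list[str]]]]
    bernoulli_crosstalk: list[tuple[str, int]]
    cluster_crosstalk: list[tuple[str, int]]
    n_bernoulli_sites: int
    expected_background_sites: float
    n_truncated_sites: int
    n_sites_emitted: int
    ordered_fraction_target: float
    ordered_fraction_emitted: float
    n_disorder_segments: int
    n_disease_motif_variants: int
    n_at_site_disease_variants: int
    at_site_p0: float
    crosstalk_fraction: float
    n_cis_records_total: int
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["planted_ptm_hotspots"] = [tuple(x) for x in payload["planted_ptm_hotspots"]]
        payload["planted_crosstalk_hotspots"] = [
            tuple(x) for x in payload["planted_crosstalk_hotspots"]
        ]
        payload["bernoulli_crosstalk"] = [tuple(x) for x in payload["bernoulli_crosstalk"]]
        payload["cluster_crosstalk"] = [tuple(x) for x in payload["cluster_crosstalk"]]
        payload["sites"] = {
            acc: [(int(p), list(t)) for p, t in lst] for acc, lst in payload["sites"].items()
        }
        return cls(**payload)


def _weighted_choice(rng: np.random.Generator, items: Sequence[str], weights: Sequence[float]) -> str:
    probs = np.asarray(weights, dtype=float)
    probs = probs / probs.sum()
    return str(items[int(rng.choice(len(items), p=probs))])


def _raw_name(ptype: str, residue: str) -> str:
    entry = RAW_NAME_BY_TYPE.get(ptype, ptype)
    if isinstance(entry, dict):
        return entry.get(residue, ptype)
    return entry


def _disorder_track(rng: np.random.Generator, length: int, cfg: GeneratorConfig) -> tuple[list[str], int]:
    """Alternating geometric-length ordered/disordered segments; returns the
    label list and the number of segments drawn."""
    f = cfg.ordered_fraction
    mean_o = cfg.mean_ordered_segment
    mean_d = max(2.0, mean_o * (1.0 - f) / f) if f > 0 else length
    labels: list[str] = []
    ordered_now = bool(rng.random() < f)
    n_segments = 0
    while len(labels) < length:
        n_segments += 1
        if ordered_now:
            seg_len = int(rng.geometric(1.0 / mean_o))
            labels.extend("O" * seg_len)
        else:
            seg_len = int(rng.geometric(1.0 / mean_d))
            lab = "DB" if rng.random() < cfg.db_fraction else "DN"
            labels.extend([lab] * seg_len)
        ordered_now = not ordered_now
    return labels[:length], n_segments


def generate(
    config: GeneratorConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> tuple[dict[str, Path], GroundTruth]:
    """Emit the complete synthetic bundle into ``out_dir``.

    Returns (paths, truth).  The bundle comprises proteome.fasta, three
    generic-dialect PTM tables split by simulated source database, five PPI
    edge tables, associations.tsv, cvd_terms.txt, disorder_tracks.tsv,
    variants.tsv, cis_crosstalk.tsv, the serialized ground truth and a
    config snapshot.  Same config + same seed => byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    letters = list(AA_LETTERS)
    aa_probs = np.array([config.aa_weights[a] for a in letters], dtype=float)
    aa_probs /= aa_probs.sum()

    seed_accs = [f"SIRT{i}" for i in range(1, config.n_seeds + 1)]
    int_accs = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]

    # --- sequences -------------------------------------------------------
    mu = math.log(config.length_mean) - config.length_sigma ** 2 / 2.0
    sequences: dict[str, list[str]] = {}
    for acc in seed_accs + int_accs:
        L = int(np.clip(round(rng.lognormal(mu, config.length_sigma)),
                        config.length_min, config.length_max))
        sequences[acc] = [letters[i] for i in rng.choice(len(letters), size=L, p=aa_probs)]

    # --- planted role assignment ----------------------------------------
    ptm_hotspot_accs = int_accs[: config.n_hotspot_proteins]
    ct_hotspot_accs = int_accs[
        config.n_hotspot_proteins:
        config.n_hotspot_proteins + config.n_crosstalk_hotspot_proteins
    ]
    remaining = int_accs[config.n_hotspot_proteins + config.n_crosstalk_hotspot_proteins:]
    hub_accs = [remaining[i] for i in rng.choice(
        len(remaining), size=min(config.n_planted_hubs, len(remaining)), replace=False)]
    hub_set = set(hub_accs)
    eligible_single = [a for a in remaining if a not in hub_set]
    n_single = int(round(config.single_source_fraction * config.n_proteins))
    n_single = min(n_single, len(eligible_single))
    single_accs = [eligible_single[i] for i in rng.choice(
        len(eligible_single), size=n_single, replace=False)]
    single_set = set(single_accs)
    single_source_of = {
        acc: PPI_SOURCE_NAMES[int(rng.integers(len(PPI_SOURCE_NAMES)))]
        for acc in single_accs
    }

    # --- PTM sites -------------------------------------------------------
    types = sorted(config.site_density)
    densities = [config.site_density[t] for t in types]
    k_types = sorted(t for t, res in config.residue_map.items() if res == "K")
    k_weights = [config.site_density.get(t, 0.01) for t in k_types]

    sites: dict[str, dict[int, set[str]]] = {}
    truth_sites: dict[str, list[tuple[int, list[str]]]] = {}
    planted_ptm_windows: list[tuple[str, int, int]] = []
    planted_ct_windows: list[tuple[str, int, int]] = []
    cluster_ct_positions: list[tuple[str, int]] = []
    bernoulli_ct_positions: list[tuple[str, int]] = []
    n_truncated = 0
    n_bernoulli_eligible = 0
    expected_background = 0.0

    for acc in int_accs:
        seq = sequences[acc]
        L = len(seq)
        here: dict[int, set[str]] = {}
        cluster_here: set[int] = set()
        expected_background += sum(densities) * L / 100.0

        if acc in ptm_hotspot_accs or acc in ct_hotspot_accs:
            is_ct_cluster = acc in ct_hotspot_accs
            n_cluster = (config.crosstalk_cluster_sites if is_ct_cluster
                         else config.cluster_sites)
            wstart = int(rng.integers(config.flank + 1,
                                      L - config.cluster_span - config.flank))
            offs = np.sort(rng.choice(config.cluster_span, size=n_cluster, replace=False))
            positions = [wstart + int(o) for o in offs]
            for pos in positions:
                if is_ct_cluster:
                    chosen = rng.choice(len(k_types), size=2, replace=False,
                                        p=np.array(k_weights) / sum(k_weights))
                    tset = {k_types[int(chosen[0])], k_types[int(chosen[1])]}
                    seq[pos - 1] = "K"
                    cluster_ct_positions.append((acc, pos))
                    cluster_here.add(pos)
                else:
                    t = _weighted_choice(rng, types, densities)
                    tset = {t}
                    seq[pos - 1] = str(rng.choice(list(config.residue_map[t])))
                here[pos] = tset
            window = (acc, positions[0], positions[-1])
            (planted_ct_windows if is_ct_cluster else planted_ptm_windows).append(window)

        # background: Poisson counts per type, positions uniform over the
        # type's permitted residues, never reusing a position (no accidental
        # cross-type collisions, so crosstalk is exactly what is planted)
        for t in types:
            lam = config.site_density[t] * L / 100.0
            count = int(rng.poisson(lam))
            if count == 0:
                continue
            allowed = [p for p in range(1, L + 1)
                       if seq[p - 1] in config.residue_map[t] and p not in here]
            take = min(count, len(allowed))
            n_truncated += count - take
            if take == 0:
                continue
            for i in rng.choice(len(allowed), size=take, replace=False):
                here[allowed[int(i)]] = {t}

        # Bernoulli second competing type (in-situ crosstalk)
        for pos in sorted(here):
            if pos in cluster_here:
                continue
            n_bernoulli_eligible += 1
            if rng.random() >= config.crosstalk_fraction:
                continue
            residue = seq[pos - 1]
            partners = [t for t, res in config.residue_map.items()
                        if residue in res and t not in here[pos]]
            if not partners:
                continue
            weights = [config.site_density.get(t, 0.01) for t in partners]
            here[pos].add(_weighted_choice(rng, sorted(partners),
                          [config.site_density.get(t, 0.01) for t in sorted(partners)]))
            bernoulli_ct_positions.append((acc, pos))
        sites[acc] = here
        truth_sites[acc] = [(pos, sorted(here[pos])) for pos in sorted(here)]

    n_sites_emitted = sum(len(v) for v in sites.values())

    # --- raw PTM records split across simulated sources ------------------
    ptm_sources = sorted(config.ptm_source_probs)
    by_source: dict[str, list[PTMSiteRaw]] = {s: [] for s in ptm_sources}
    for acc in int_accs:
        seq = sequences[acc]
        for pos in sorted(sites[acc]):
            for t in sorted(sites[acc][pos]):
                residue = seq[pos - 1]
                chosen = [s for s in ptm_sources
                          if rng.random() < config.ptm_source_probs[s]]
                if not chosen:
                    chosen = [ptm_sources[int(rng.integers(len(ptm_sources)))]]
                for s in chosen:
                    by_source[s].append(
                        PTMSiteRaw(acc, pos, residue, _raw_name(t, residue), s)
                    )

    # --- PPI edges --------------------------------------------------------
    multi_accs = [a for a in int_accs if a not in single_set]
    edges: set[tuple[str, str]] = set()
    for acc in int_accs:
        n_seed_links = 1 + int(rng.binomial(2, 0.25))
        for i in rng.choice(config.n_seeds, size=n_seed_links, replace=False):
            edges.add(tuple(sorted((acc, seed_accs[int(i)]))))
        if acc in single_set:
            continue  # single-source proteins link only to seeds
        n_partners = int(rng.poisson(config.interactor_edge_rate))
        for _ in range(n_partners):
            other = multi_accs[int(rng.integers(len(multi_accs)))]
            if other != acc:
                edges.add(tuple(sorted((acc, other))))
    for acc in hub_accs:
        pool = [a for a in multi_accs if a != acc]
        for i in rng.choice(len(pool), size=min(config.hub_extra_degree, len(pool)),
                            replace=False):
            edges.add(tuple(sorted((acc, pool[int(i)]))))

    edges_by_source: dict[str, list[InteractionEdgeRaw]] = {s: [] for s in PPI_SOURCE_NAMES}
    for a, b in sorted(edges):
        singles = [x for x in (a, b) if x in single_set]
        if singles:
            srcs = [single_source_of[singles[0]]]
        else:
            srcs = [s for s in PPI_SOURCE_NAMES
                    if rng.random() < config.ppi_source_probs[s]]
            while len(srcs) < 2:  # multi-source proteins must pass the 2-DB rule
                extra = PPI_SOURCE_NAMES[int(rng.integers(len(PPI_SOURCE_NAMES)))]
                if extra not in srcs:
                    srcs.append(extra)
        for s in srcs:
            edges_by_source[s].append(InteractionEdgeRaw(a, b, s))

    # --- disease categories and associations ----------------------------
    cvd_terms = sorted(disease_classify.default_cvd_terms().exact)
    categories: dict[str, str] = {}
    assoc_rows: list[tuple[str, str]] = []
    nd_prob = 1.0 - config.cvd_prob - config.od_prob
    for acc in int_accs:
        cat = str(rng.choice(["CVD", "OD", "ND"],
                             p=[config.cvd_prob, config.od_prob, nd_prob]))
        categories[acc] = cat
        if cat == "CVD":
            n_cvd = 1 + int(rng.poisson(0.5))
            for i in rng.choice(len(cvd_terms), size=min(n_cvd, len(cvd_terms)),
                                replace=False):
                assoc_rows.append((acc, cvd_terms[int(i)]))
            n_other = int(rng.poisson(config.other_disease_rate))
            for i in rng.choice(len(OTHER_DISEASES), size=min(n_other, len(OTHER_DISEASES)),
                                replace=False):
                assoc_rows.append((acc, OTHER_DISEASES[int(i)]))
        elif cat == "OD":
            n_other = 1 + int(rng.poisson(1.0))
            for i in rng.choice(len(OTHER_DISEASES), size=min(n_other, len(OTHER_DISEASES)),
                                replace=False):
                assoc_rows.append((acc, OTHER_DISEASES[int(i)]))

    # --- disorder tracks -------------------------------------------------
    tracks: dict[str, list[str]] = {}
    n_segments_total = 0
    n_ordered_residues = 0
    n_residues = 0
    for acc in int_accs:
        lab, n_seg = _disorder_track(rng, len(sequences[acc]), config)
        tracks[acc] = lab
        n_segments_total += n_seg
        n_ordered_residues += sum(1 for c in lab if c == "O")
        n_residues += len(lab)

    # --- variants --------------------------------------------------------
    variants: list[VariantRecord] = []
    seen_keys: set[tuple] = set()
    n_disease_scheme = 0
    n_at_site = 0
    for acc in int_accs:
        seq = sequences[acc]
        L = len(seq)
        site_positions = sorted(sites[acc])
        n_var = int(rng.poisson(config.variants_per_protein))
        for _ in range(n_var):
            cls = str(rng.choice(
                ["disease", "polymorphism", "unclassified"],
                p=[config.variant_class_probs["disease"],
                   config.variant_class_probs["polymorphism"],
                   config.variant_class_probs["unclassified"]],
            ))
            at_site_flag = False
            if cls == "disease" and site_positions:
                anchor = site_positions[int(rng.integers(len(site_positions)))]
                if rng.random() < config.at_site_p0:
                    pos = anchor
                    at_site_flag = True
                else:
                    candidates = [anchor + d for d in range(-config.flank, config.flank + 1)
                                  if d != 0 and 1 <= anchor + d <= L
                                  and (anchor + d) not in sites[acc]]
                    if not candidates:
                        continue
                    pos = candidates[int(rng.integers(len(candidates)))]
            else:
                pos = int(rng.integers(1, L + 1))
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in letters if a != ref]))
            key = (acc, pos, ref, alt)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            variants.append(VariantRecord(acc, pos, ref, alt, cls))
            if cls == "disease" and site_positions:
                n_disease_scheme += 1
                if at_site_flag:
                    n_at_site += 1

    # --- cis-crosstalk records -------------------------------------------
    cis: list[CisCrosstalkRecord] = []
    for acc in int_accs:
        positions = sorted(sites[acc])
        if len(positions) < 2:
            continue
        for _ in range(int(rng.poisson(config.cis_per_protein))):
            i, j = rng.choice(len(positions), size=2, replace=False)
            score = round(float(rng.uniform(config.cis_score_low, config.cis_score_high)), 1)
            cis.append(CisCrosstalkRecord(acc, positions[int(i)], positions[int(j)], score))

    # --- emit -------------------------------------------------------------
    proteome = [
        ProteinRecord(acc, "", "".join(sequences[acc])) for acc in seed_accs + int_accs
    ]
    paths: dict[str, Path] = {}

    paths["fasta"] = out_dir / "proteome.fasta"
    write_fasta(proteome, paths["fasta"])

    for s in ptm_sources:
        p = out_dir / f"ptm_{s}.tsv"
        write_ptm_table(by_source[s], p)
        paths[f"ptm_{s}"] = p
    for s in PPI_SOURCE_NAMES:
        p = out_dir / f"ppi_{s}.tsv"
        write_interaction_table(edges_by_source[s], p)
        paths[f"ppi_{s}"] = p

    import pandas as pd

    paths["associations"] = out_dir / "associations.tsv"
    write_table(
        pd.DataFrame(assoc_rows, columns=["gene_or_accession", "disease_name"]),
        paths["associations"],
    )
    paths["cvd_terms"] = out_dir / "cvd_terms.txt"
    from importlib.resources import files

    paths["cvd_terms"].write_text(
        files("ptmatlas.data").joinpath("cvd_terms.txt").read_text(encoding="utf-8"),
        encoding="utf-8",
    )
    paths["disorder"] = out_dir / "disorder_tracks.tsv"
    write_disorder_labels(tracks, paths["disorder"])
    paths["variants"] = out_dir / "variants.tsv"
    write_variants(variants, paths["variants"])
    paths["cis"] = out_dir / "cis_crosstalk.tsv"
    write_cis_crosstalk(cis, paths["cis"])
    paths["seeds"] = out_dir / "seed_proteins.txt"
    paths["seeds"].write_text("\n".join(seed_accs) + "\n", encoding="utf-8")

    truth = GroundTruth(
        categories=categories,
        planted_ptm_hotspots=planted_ptm_windows,
        planted_crosstalk_hotspots=planted_ct_windows,
        planted_hubs=sorted(hub_accs),
        consensus_accessions=sorted(set(seed_accs) | (set(int_accs) - single_set)),
        single_source_accessions=sorted(single_accs),
        sites=truth_sites,
        bernoulli_crosstalk=sorted(bernoulli_ct_positions),
        cluster_crosstalk=sorted(cluster_ct_positions),
        n_bernoulli_sites=n_bernoulli_eligible,
        expected_background_sites=expected_background,
        n_truncated_sites=n_truncated,
        n_sites_emitted=n_sites_emitted,
        ordered_fraction_target=config.ordered_fraction,
        ordered_fraction_emitted=n_ordered_residues / n_residues if n_residues else 0.0,
        n_disorder_segments=n_segments_total,
        n_disease_motif_variants=n_disease_scheme,
        n_at_site_disease_variants=n_at_site,
        at_site_p0=config.at_site_p0,
        crosstalk_fraction=config.crosstalk_fraction,
        n_cis_records_total=len(cis),
        config=dataclasses.asdict(config),
    )
    paths["truth"] = out_dir / "ground_truth.json"
    truth.to_json(paths["truth"])
    paths["config"] = out_dir / "generator_config.json"
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
    return paths, truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def _poisson_tail(lam: float, k: int) -> float:
    """P(Poisson(lam) >= k)."""
    if k <= 0:
        return 1.0
    acc = 0.0
    term = math.exp(-lam)
    for i in range(k):
        acc += term
        term *= lam / (i + 1)
    return max(0.0, 1.0 - acc)


def _overlaps(region, start: int, end: int) -> bool:
    return region.start <= end and start <= region.end


def verify_recovery(truth: GroundTruth, outputs: Mapping) -> dict:
    """Score the pipeline outputs against the planted ground truth.

    ``outputs`` must contain ``catalog`` (list of PTMSite), ``scans``
    (accession -> the dict from :func:`ptmatlas.motif_hotspot.scan_protein`),
    ``sequence_lengths`` and may contain ``network``
    (:class:`~ptmatlas.network.ConsensusNetwork`), ``assignments``
    (disease classification) and ``variant_flags`` / ``mavs`` from the
    variant stage.  Returns a flat report dict.

    False-positive bounds are model-based: for a background protein with s
    sites on length L, the chance any window qualifies is approximated by
    1 - (1 - p_w)^s with p_w a Poisson window-count tail; the report gives
    the summed expectation and its standard deviation so observed counts
    can be checked against expectation + 3 SD.
    """
    if "catalog" not in outputs or "scans" not in outputs:
        raise ValueError("outputs must contain 'catalog' and 'scans'")
    catalog = outputs["catalog"]
    scans = outputs["scans"]
    lengths = outputs["sequence_lengths"]
    cfg = truth.config
    flank = cfg.get("flank", 7)
    report: dict = {}

    # hotspot sensitivity
    def _sensitivity(windows, kind):
        hits = 0
        for acc, start, end in windows:
            regions = scans.get(acc, {}).get(f"{kind}_regions", [])
            if any(_overlaps(r, start, end) for r in regions):
                hits += 1
        return hits / len(windows) if windows else float("nan")

    report["ptm_hotspot_sensitivity"] = _sensitivity(truth.planted_ptm_hotspots, "ptm")
    report["crosstalk_hotspot_sensitivity"] = _sensitivity(
        truth.planted_crosstalk_hotspots, "crosstalk")

    planted_accs = {w[0] for w in truth.planted_ptm_hotspots} | {
        w[0] for w in truth.planted_crosstalk_hotspots}
    background = [acc for acc in truth.sites if acc not in planted_accs]

    sites_by_acc: dict[str, list] = {}
    for s in catalog:
        sites_by_acc.setdefault(s.accession, []).append(s)

    k_ptm = 5
    k_ct = 3
    for kind, k, center_included in (("ptm", k_ptm, False), ("crosstalk", k_ct, True)):
        n_fp = 0
        expectation = 0.0
        variance = 0.0
        for acc in background:
            res = scans.get(acc)
            if res and res[f"{kind}_motifs"]:
                n_fp += 1
            ssites = sites_by_acc.get(acc, [])
            if kind == "ptm":
                n_rel = len(ssites)
            else:
                n_rel = sum(1 for s in ssites if s.is_crosstalk)
            L = lengths.get(acc, 1)
            if n_rel == 0:
                continue
            lam = max(0, n_rel - 1) * 2 * flank / L
            need = k if not center_included else k - 1
            p_w = _poisson_tail(lam, need)
            p_prot = 1.0 - (1.0 - p_w) ** n_rel
            expectation += p_prot
            variance += p_prot * (1.0 - p_prot)
        report[f"{kind}_false_positive_proteins"] = n_fp
        report[f"{kind}_fp_expected"] = expectation
        report[f"{kind}_fp_sd"] = math.sqrt(variance)

    # crosstalk site recovery and fraction
    detected_ct = {(s.accession, s.position) for s in catalog if s.is_crosstalk}
    planted_ct = set(truth.bernoulli_crosstalk) | set(truth.cluster_crosstalk)
    report["crosstalk_site_recovery"] = (
        len(planted_ct & detected_ct) / len(planted_ct) if planted_ct else float("nan")
    )
    cluster_set = set(truth.cluster_crosstalk)
    n_total = sum(1 for s in catalog if (s.accession, s.position) not in cluster_set)
    n_ct = sum(1 for s in catalog
               if s.is_crosstalk and (s.accession, s.position) not in cluster_set)
    report["crosstalk_fraction_recovered"] = n_ct / n_total if n_total else float("nan")
    report["crosstalk_fraction_target"] = truth.crosstalk_fraction
    report["n_sites_recovered"] = len(catalog)

    net = outputs.get("network")
    if net is not None:
        want = set(truth.consensus_accessions)
        got = set(net.nodes)
        report["consensus_node_recovery"] = len(want & got) / len(want)
        report["consensus_false_nodes"] = len(got - want)
        report["hub_recovery"] = (
            len(set(truth.planted_hubs) & net.hubs) / len(truth.planted_hubs)
            if truth.planted_hubs else float("nan")
        )

    assignments = outputs.get("assignments")
    if assignments is not None:
        agree = sum(
            1 for a in assignments if truth.categories.get(a.accession) == a.category
        )
        report["disease_category_agreement"] = agree / len(assignments)

    flags = outputs.get("variant_flags")
    mavs = outputs.get("mavs")
    if flags is not None and mavs is not None:
        disease_mav_keys = {
            m.variant.key for m in mavs if m.variant.classification == "disease"
        }
        at_site_keys = {
            m.variant.key for m in mavs
            if m.variant.classification == "disease" and m.at_site
        }
        n_den = len(disease_mav_keys)
        report["at_site_disease_fraction"] = (
            len(at_site_keys) / n_den if n_den else float("nan")
        )
        report["at_site_p0_target"] = truth.at_site_p0
        report["n_disease_motif_variants"] = n_den
    return report
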