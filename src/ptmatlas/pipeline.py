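"""End-to-end orchestration: simulate/ingest, network, catalog, classify,
disorder, hotspots, variants, report.

Stages communicate only via TSV files in the output tree, so each stage is
independently inspectable and re-runnable; ``run_all`` also returns the
in-memory objects for programmatic use.  A run manifest records the config
snapshot, input checksums, per-stage row counts and the software version;
re-running with identical inputs reproduces identical data tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import disease_classify, disorder_map, io_integration as io, motif_hotspot
from . import network as network_mod
from . import ptm_catalog, synthetic_data, variant_map

logger = logging.getLogger("ptmatlas.pipeline")

PROFILE_SUBJECTS = ("phosphorylation", "acetylation", "ubiquitination", "methylation")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(config: Mapping, key: str):
    if key not in config:
        raise io.ConfigError(f"configuration is missing required key {key!r}")
    return config[key]


def simulate_inputs(out_dir: Path, seed: int = 0, generator_overrides: Mapping | None = None):
    """Generate the synthetic bundle under ``out_dir/inputs`` and return a
    pipeline input configuration pointing at it."""
    overrides = dict(generator_overrides or {})
    overrides["seed"] = seed
    gen_cfg = synthetic_data.default_config(**overrides)
    input_dir = out_dir / "inputs"
    paths, truth = synthetic_data.generate(gen_cfg, input_dir)
    cfg = {
        "fasta": str(paths["fasta"]),
        "seeds_file": str(paths["seeds"]),
        "ptm_tables": [
            {"path": str(paths[f"ptm_{s}"]), "dialect": "generic"}
            for s in sorted(gen_cfg.ptm_source_probs)
        ],
        "ppi_tables": {
            s: str(paths[f"ppi_{s}"]) for s in synthetic_data.PPI_SOURCE_NAMES
        },
        "associations": str(paths["associations"]),
        "cvd_terms": str(paths["cvd_terms"]),
        "disorder_tracks": str(paths["disorder"]),
        "variants": str(paths["variants"]),
        "cis_crosstalk": str(paths["cis"]),
    }
    return cfg, truth


def run_all(
    config: Mapping,
    out_dir: str | Path,
    simulate: bool = False,
    seed: int = 0,
    generator_overrides: Mapping | None = None,
) -> dict:
    """Execute the full analysis; returns the in-memory results dict.

    ``config`` names every input path (see the README for the schema) unless
    ``simulate`` is set, in which case the synthetic bundle is generated
    first and analysed in place.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})
    truth = None
    if simulate:
        sim_cfg, truth = simulate_inputs(out_dir, seed=seed,
                                         generator_overrides=generator_overrides)
        sim_cfg.update({k: v for k, v in config.items() if k not in sim_cfg})
        config = {**config, **sim_cfg}

    params = config.get("params", {})
    flank = int(params.get("flank", motif_hotspot.DEFAULT_FLANK))
    k_ptm = int(params.get("k_ptm", motif_hotspot.DEFAULT_K_PTM))
    k_ct = int(params.get("k_crosstalk", motif_hotspot.DEFAULT_K_CROSSTALK))
    percentile = float(params.get("hub_percentile", 75.0))
    min_cis = float(params.get("min_cis_score", 80.0))
    include_center = bool(params.get("crosstalk_include_center", True))
    report_threshold = int(params.get("hotspot_report_threshold", 10))

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "params": {
            "flank": flank, "k_ptm": k_ptm, "k_crosstalk": k_ct,
            "hub_percentile": percentile, "min_cis_score": min_cis,
            "crosstalk_include_center": include_center,
        },
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    # --- inputs -----------------------------------------------------------
    fasta_path = _require(config, "fasta")
    proteome_list = io.read_fasta(fasta_path)
    proteome = {p.accession: p for p in proteome_list}
    manifest["inputs"]["fasta"] = _sha256(Path(fasta_path))

    seeds = config.get("seeds")
    if seeds is None:
        seeds_file = _require(config, "seeds_file")
        seeds = [
            line.strip()
            for line in Path(seeds_file).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]

    # --- network ----------------------------------------------------------
    edge_lists = {
        source: io.read_interaction_table(path, source)
        for source, path in _require(config, "ppi_tables").items()
    }
    net = network_mod.build_consensus_network(edge_lists, seeds, percentile=percentile)
    nodes_frame = pd.DataFrame(
        [
            (
                acc,
                ";".join(sorted(net.node_sources.get(acc, set()))),
                net.degree[acc],
                acc in net.hubs,
            )
            for acc in sorted(net.nodes)
        ],
        columns=["accession", "sources", "degree", "is_hub"],
    )
    io.write_table(nodes_frame, out_dir / "nodes.tsv")
    edges_frame = pd.DataFrame(sorted(net.edges), columns=["accession_a", "accession_b"])
    io.write_table(edges_frame, out_dir / "edges.tsv")
    manifest["stages"]["network"] = {
        "n_nodes": len(net.nodes), "n_edges": len(net.edges),
        "hub_threshold": net.hub_threshold, "n_hubs": len(net.hubs),
    }

    # --- catalog ----------------------------------------------------------
    raw_sites = []
    for entry in _require(config, "ptm_tables"):
        raw_sites.extend(io.read_ptm_table(entry["path"], entry.get("dialect", "generic")))
    name_map = None
    if config.get("ptm_name_map"):
        name_map = ptm_catalog.load_ptm_name_map(config["ptm_name_map"])
    catalog = ptm_catalog.build_catalog(raw_sites, proteome, name_map)
    io.write_table(ptm_catalog.catalog_to_frame(catalog), out_dir / "catalog.tsv")
    crosstalk = ptm_catalog.find_crosstalk_sites(catalog)
    census, hist = ptm_catalog.crosstalk_census(crosstalk)
    io.write_table(census, out_dir / "census.tsv")
    io.write_table(hist, out_dir / "census_histogram.tsv")
    summaries, global_summary = ptm_catalog.summarize_proteins(catalog)
    summary_frame = pd.DataFrame(
        [
            (s.accession, s.n_sites, s.n_types, s.n_crosstalk_sites)
            for s in summaries
        ],
        columns=["accession", "n_sites", "n_types", "n_crosstalk_sites"],
    )
    io.write_table(summary_frame, out_dir / "protein_summary.tsv")
    manifest["stages"]["catalog"] = {
        "n_raw_records": len(raw_sites),
        "n_sites": len(catalog),
        "n_crosstalk_sites": len(crosstalk),
    }

    # --- disease classification ------------------------------------------
    associations = io.read_disease_table(_require(config, "associations"))
    if config.get("gene_mapping"):
        mapping = io.read_gene_mapping(config["gene_mapping"])
        associations = io.apply_gene_mapping(associations, mapping, set(proteome))
    cvd_terms = disease_classify.load_cvd_terms(_require(config, "cvd_terms"))
    universe = sorted({s.accession for s in catalog})
    assignments = disease_classify.classify(associations, cvd_terms, universe)
    assign_frame = pd.DataFrame(
        [
            (a.accession, a.category, a.n_associations,
             ";".join(sorted(a.matched_cvd_terms)))
            for a in assignments
        ],
        columns=["accession", "category", "n_associations", "matched_cvd_terms"],
    )
    io.write_table(assign_frame, out_dir / "disease_categories.tsv")
    manifest["stages"]["classify"] = disease_classify.category_counts(assignments)
    categories = disease_classify.category_of(assignments)

    # --- disorder ---------------------------------------------------------
    labels = io.read_disorder_labels(_require(config, "disorder_tracks"))
    tracks = disorder_map.tracks_from_labels(labels, proteome=proteome)
    site_labels, fractions = disorder_map.assign_structural_category(catalog, tracks)
    io.write_table(fractions, out_dir / "disorder_fractions.tsv")
    site_label_frame = pd.DataFrame(
        [(acc, pos, lab) for (acc, pos), lab in sorted(site_labels.items())],
        columns=["accession", "position", "structural_category"],
    )
    io.write_table(site_label_frame, out_dir / "site_structural_categories.tsv")
    ct_disorder = disorder_map.crosstalk_disorder_summary(crosstalk, tracks)
    io.write_table(ct_disorder, out_dir / "crosstalk_disorder.tsv")
    manifest["stages"]["disorder"] = {"n_tracks": len(tracks)}

    # --- hotspots ---------------------------------------------------------
    sites_by_protein: dict[str, list] = {}
    for s in catalog:
        sites_by_protein.setdefault(s.accession, []).append(s)
    lengths = {acc: len(p.sequence) for acc, p in proteome.items()}
    scans = {
        acc: motif_hotspot.scan_protein(
            sites, lengths.get(acc, max(x.position for x in sites)),
            k_ptm=k_ptm, k_crosstalk=k_ct, flank=flank,
            crosstalk_include_center=include_center,
        )
        for acc, sites in sites_by_protein.items()
    }
    center_rows, region_rows = [], []
    for acc in sorted(scans):
        res = scans[acc]
        for kind in ("ptm", "crosstalk"):
            for m in res[f"{kind}_motifs"]:
                center_rows.append(
                    (acc, kind, m.center, m.window_start, m.window_end)
                )
            for r in res[f"{kind}_regions"]:
                region_rows.append((acc, r.start, r.end, kind, r.n_qualifying_centers))
    io.write_table(
        pd.DataFrame(center_rows,
                     columns=["accession", "kind", "center", "window_start", "window_end"]),
        out_dir / "hotspot_centers.tsv",
    )
    io.write_table(
        pd.DataFrame(region_rows,
                     columns=["accession", "start", "end", "kind", "n_centers"]),
        out_dir / "hotspot_regions.tsv",
    )
    hs_summaries, cohorts = motif_hotspot.hotspot_summary(scans, lengths, categories)
    hs_frame = pd.DataFrame(
        [
            (
                h.accession, h.n_ptm_hotspot_centers, h.n_crosstalk_hotspot_centers,
                round(h.ptm_coverage, 6), round(h.crosstalk_coverage, 6),
                "" if h.ratio is None else round(h.ratio, 6),
            )
            for h in hs_summaries
        ],
        columns=["accession", "n_ptm_hotspot_centers", "n_crosstalk_hotspot_centers",
                 "ptm_coverage", "crosstalk_coverage", "crosstalk_ptm_ratio"],
    )
    io.write_table(hs_frame, out_dir / "hotspot_summary.tsv")
    profiles = []
    for subject in PROFILE_SUBJECTS:
        for mode in (False, True):
            profiles.append(
                motif_hotspot.positional_profile(
                    catalog, subject, include_center=mode, flank=flank
                )
            )
    io.write_table(motif_hotspot.profiles_to_frame(profiles), out_dir / "profiles.tsv")
    manifest["stages"]["hotspots"] = {
        "n_ptm_hotspot_proteins": len(cohorts["proteins_with_ptm_hotspots"]),
        "n_crosstalk_hotspot_proteins": len(cohorts["proteins_with_crosstalk_hotspots"]),
        "n_both": len(cohorts["proteins_with_both"]),
    }

    # --- variants ---------------------------------------------------------
    variants = variant_map.read_variants(_require(config, "variants"))
    mavs, flags = variant_map.map_mavs(variants, catalog, flank=flank, proteome=proteome)
    io.write_table(flags, out_dir / "variant_flags.tsv")
    mav_frame = pd.DataFrame(
        [
            (
                m.variant.accession, m.variant.position, m.variant.ref_aa,
                m.variant.alt_aa, m.variant.classification, m.site_position,
                m.offset, m.at_site, m.site_is_crosstalk,
                ";".join(sorted(m.site_types)), m.ref_matches_sequence,
            )
            for m in mavs
        ],
        columns=["accession", "position", "ref", "alt", "class", "site_position",
                 "offset", "at_site", "site_is_crosstalk", "site_types", "ref_matches"],
    )
    io.write_table(mav_frame, out_dir / "mavs.tsv")
    region_lookup = {
        acc: {"ptm": scans[acc]["ptm_regions"], "crosstalk": scans[acc]["crosstalk_regions"]}
        for acc in scans
    }
    mav_tables = variant_map.mav_summaries(
        mavs, flags, categories=categories, site_labels=site_labels,
        hotspot_regions=region_lookup, flank=flank,
        hotspot_report_threshold=report_threshold,
    )
    for name, frame in mav_tables.items():
        io.write_table(frame, out_dir / f"mav_summary_{name}.tsv")
    manifest["stages"]["variants"] = {
        "n_variants": len(flags), "n_mav_pairs": len(mavs),
        "n_mav_variants": int(flags["is_mav"].sum()),
    }

    # --- cis crosstalk ingest (count only; deeper analysis out of scope) --
    cis_records = []
    if config.get("cis_crosstalk"):
        cis_records = io.read_cis_crosstalk(config["cis_crosstalk"], min_score=min_cis)
        manifest["stages"]["cis"] = {"n_records_kept": len(cis_records)}

    results = {
        "config": config,
        "proteome": proteome,
        "network": net,
        "catalog": catalog,
        "crosstalk": crosstalk,
        "assignments": assignments,
        "categories": categories,
        "tracks": tracks,
        "site_labels": site_labels,
        "scans": scans,
        "sequence_lengths": lengths,
        "hotspot_summaries": hs_summaries,
        "cohorts": cohorts,
        "mavs": mavs,
        "variant_flags": flags,
        "cis": cis_records,
        "global_summary": global_summary,
        "truth": truth,
        "out_dir": out_dir,
    }

    report(results, out_dir)

    for p in sorted(out_dir.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def report(results: Mapping, out_dir: str | Path) -> pd.DataFrame:
    """Emit the overview tables: the interactor funnel, the disease split
    overall and within hotspot cohorts, and headline counts."""
    out_dir = Path(out_dir)
    net = results["network"]
    catalog = results["catalog"]
    cohorts = results["cohorts"]
    categories = results["categories"]

    seeds = {n for n in net.nodes if n.startswith("SIRT")}
    interactors = set(net.nodes) - seeds
    with_ptm = {s.accession for s in catalog}
    with_acetyl = {s.accession for s in catalog if "acetylation" in s.types}
    with_ct = {s.accession for s in catalog if s.is_crosstalk}

    rows = [
        ("n_interactors", len(interactors)),
        ("n_interactors_with_ptm", len(interactors & with_ptm)),
        ("n_interactors_with_acetylation", len(interactors & with_acetyl)),
        ("n_interactors_with_crosstalk", len(interactors & with_ct)),
        ("n_catalog_proteins", len(with_ptm)),
        ("n_catalog_sites", len(catalog)),
        ("n_crosstalk_sites", len(results["crosstalk"])),
        ("n_hubs", len(net.hubs)),
        ("hub_threshold", net.hub_threshold),
        ("mean_sites_per_protein",
         round(results["global_summary"]["mean_sites_per_protein"], 4)),
        ("mean_types_per_protein",
         round(results["global_summary"]["mean_types_per_protein"], 4)),
    ]
    for cat in disease_classify.CATEGORIES:
        rows.append((f"n_{cat}", sum(1 for c in categories.values() if c == cat)))
    for name in ("proteins_with_ptm_hotspots", "proteins_with_crosstalk_hotspots",
                 "proteins_with_both", "proteins_crosstalk_only"):
        rows.append((f"n_{name}", len(cohorts[name])))
    overview = pd.DataFrame(rows, columns=["metric", "value"], dtype=object)
    io.write_table(overview, out_dir / "report_overview.tsv")

    split_rows = []
    for name in ("proteins_with_ptm_hotspots", "proteins_with_crosstalk_hotspots"):
        for cat in disease_classify.CATEGORIES:
            n = sum(1 for acc in cohorts[name] if categories.get(acc, "ND") == cat)
            split_rows.append((name, cat, n))
    io.write_table(
        pd.DataFrame(split_rows, columns=["cohort", "category", "n_proteins"]),
        out_dir / "report_hotspot_disease_split.tsv",
    )
    return overview


# ---------------------------------------------------------------------------
# reload for recovery verification
# ---------------------------------------------------------------------------

def load_results(out_dir: str | Path, input_dir: str | Path | None = None) -> dict:
    """Reconstruct the objects needed by
    :func:`ptmatlas.synthetic_data.verify_recovery` from a completed run
    directory (and its ``inputs`` subdirectory by default)."""
    out_dir = Path(out_dir)
    input_dir = Path(input_dir) if input_dir else out_dir / "inputs"
    proteome = {p.accession: p for p in io.read_fasta(input_dir / "proteome.fasta")}
    lengths = {acc: len(p.sequence) for acc, p in proteome.items()}
    catalog = ptm_catalog.frame_to_catalog(io.read_table(out_dir / "catalog.tsv"))

    with open(out_dir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    params = manifest["params"]
    sites_by_protein: dict[str, list] = {}
    for s in catalog:
        sites_by_protein.setdefault(s.accession, []).append(s)
    scans = {
        acc: motif_hotspot.scan_protein(
            sites, lengths[acc], k_ptm=params["k_ptm"], k_crosstalk=params["k_crosstalk"],
            flank=params["flank"],
            crosstalk_include_center=params["crosstalk_include_center"],
        )
        for acc, sites in sites_by_protein.items()
    }

    nodes = io.read_table(out_dir / "nodes.tsv")
    edges = io.read_table(out_dir / "edges.tsv")
    net = network_mod.ConsensusNetwork(
        nodes=set(nodes["accession"]),
        edges={tuple(sorted((a, b))) for a, b in
               zip(edges["accession_a"], edges["accession_b"])},
        node_sources={
            row.accession: set(row.sources.split(";")) if row.sources else set()
            for row in nodes.itertuples(index=False)
        },
        hubs={row.accession for row in nodes.itertuples(index=False)
              if str(row.is_hub) == "True"},
    )
    net.compute_degrees()

    assign = io.read_table(out_dir / "disease_categories.tsv")
    assignments = [
        disease_classify.DiseaseCategoryAssignment(
            accession=row.accession,
            category=row.category,
            matched_cvd_terms=frozenset(
                row.matched_cvd_terms.split(";")) if row.matched_cvd_terms else frozenset(),
            n_associations=int(row.n_associations),
        )
        for row in assign.itertuples(index=False)
    ]

    mav_frame = io.read_table(out_dir / "mavs.tsv")
    mavs = [
        variant_map.MotifAssociatedVariant(
            variant=variant_map.VariantRecord(
                row.accession, int(row.position), row.ref, row.alt, row._4
            ),
            site_accession=row.accession,
            site_position=int(row.site_position),
            offset=int(row.offset),
            at_site=str(row.at_site) == "True",
            site_is_crosstalk=str(row.site_is_crosstalk) == "True",
            site_types=frozenset(str(row.site_types).split(";")),
            ref_matches_sequence=str(row.ref_matches) == "True",
        )
        for row in mav_frame.itertuples(index=False)
    ]
    flags = io.read_table(out_dir / "variant_flags.tsv")
    flags["is_mav"] = flags["is_mav"] == "True"

    truth = None
    truth_path = input_dir / "ground_truth.json"
    if truth_path.exists():
        truth = synthetic_data.GroundTruth.from_json(truth_path)

    return {
        "proteome": proteome,
        "sequence_lengths": lengths,
        "catalog": catalog,
        "scans": scans,
        "network": net,
        "assignments": assignments,
        "mavs": mavs,
        "variant_flags": flags,
        "truth": truth,
    }
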