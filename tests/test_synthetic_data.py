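"""Generator contracts: determinism, planted structure, constraint maps."""

import math
from pathlib import Path

import pytest

from ptmatlas import synthetic_data as sd
from ptmatlas.io_integration import read_fasta, read_ptm_table
from ptmatlas.ptm_catalog import build_catalog, canonicalize_ptm_name

SMALL = dict(n_proteins=40, n_hotspot_proteins=3, n_crosstalk_hotspot_proteins=2,
             n_planted_hubs=3)


def _read_all_sites(cfg, paths):
    raw = []
    for s in sorted(cfg.ptm_source_probs):
        raw.extend(read_ptm_table(paths[f"ptm_{s}"]))
    return raw


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = sd.default_config(seed=11, **SMALL)
        sd.generate(cfg, tmp_path / "a")
        sd.generate(sd.default_config(seed=11, **SMALL), tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        assert files_a
        for fa in files_a:
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seed_differs(self, tmp_path):
        sd.generate(sd.default_config(seed=1, **SMALL), tmp_path / "a")
        sd.generate(sd.default_config(seed=2, **SMALL), tmp_path / "b")
        assert ((tmp_path / "a" / "proteome.fasta").read_bytes()
                != (tmp_path / "b" / "proteome.fasta").read_bytes())


class TestPlantedStructure:
    def test_zero_crosstalk_fraction_means_no_bernoulli_sites(self, tmp_path):
        cfg = sd.default_config(seed=3, crosstalk_fraction=0.0,
                                n_crosstalk_hotspot_proteins=0, **{
                                    k: v for k, v in SMALL.items()
                                    if k != "n_crosstalk_hotspot_proteins"})
        _, truth = sd.generate(cfg, tmp_path)
        assert truth.bernoulli_crosstalk == []
        assert truth.cluster_crosstalk == []

    def test_planted_window_counts(self, tmp_path):
        cfg = sd.default_config(seed=4, **SMALL)
        _, truth = sd.generate(cfg, tmp_path)
        assert len(truth.planted_ptm_hotspots) == SMALL["n_hotspot_proteins"]
        assert len(truth.planted_crosstalk_hotspots) == SMALL["n_crosstalk_hotspot_proteins"]
        for acc, start, end in truth.planted_ptm_hotspots:
            assert end - start + 1 <= cfg.cluster_span

    def test_infeasible_cluster_rejected_before_writing(self, tmp_path):
        cfg = sd.default_config(cluster_sites=20, cluster_span=8)
        with pytest.raises(ValueError, match="cannot fit"):
            sd.generate(cfg, tmp_path / "x")
        assert not (tmp_path / "x").exists() or not any((tmp_path / "x").iterdir())

    def test_truth_sites_match_emitted_records(self, tmp_path):
        cfg = sd.default_config(seed=5, **SMALL)
        paths, truth = sd.generate(cfg, tmp_path)
        raw = _read_all_sites(cfg, paths)
        emitted = {(r.accession, r.position) for r in raw}
        planted = {(acc, pos) for acc, lst in truth.sites.items() for pos, _ in lst}
        assert emitted == planted


class TestConstraintConsistency:
    def test_residues_honour_constraint_map_and_fasta(self, tmp_path):
        cfg = sd.default_config(seed=6, **SMALL)
        paths, _ = sd.generate(cfg, tmp_path)
        proteome = {p.accession: p for p in read_fasta(paths["fasta"])}
        raw = _read_all_sites(cfg, paths)
        assert raw
        for rec in raw:
            seq_res = proteome[rec.accession].sequence[rec.position - 1]
            assert rec.residue == seq_res
            canonical = canonicalize_ptm_name(rec.ptm_name_raw)
            assert seq_res in cfg.residue_map[canonical], (rec, canonical)

    def test_mean_sites_within_three_se(self, tmp_path):
        cfg = sd.default_config(seed=8)
        paths, truth = sd.generate(cfg, tmp_path)
        catalog = build_catalog(_read_all_sites(cfg, paths))
        expected = (truth.expected_background_sites
                    + cfg.n_hotspot_proteins * cfg.cluster_sites
                    + cfg.n_crosstalk_hotspot_proteins * cfg.crosstalk_cluster_sites
                    - truth.n_truncated_sites)
        se = math.sqrt(truth.expected_background_sites)
        assert abs(len(catalog) - expected) <= 3 * se
        assert len(catalog) == truth.n_sites_emitted


def test_truth_json_roundtrip(tmp_path):
    cfg = sd.default_config(seed=9, **SMALL)
    paths, truth = sd.generate(cfg, tmp_path)
    back = sd.GroundTruth.from_json(paths["truth"])
    assert back.planted_ptm_hotspots == truth.planted_ptm_hotspots
    assert back.sites == truth.sites
    assert back.categories == truth.categories


def test_compendium_preset_site_shape(tmp_path):
    """The dense preset keeps the canonical abundance ordering:
    phosphorylation >> ubiquitination >= acetylation."""
    cfg = sd.compendium_config(seed=10, n_proteins=60, n_hotspot_proteins=0,
                               n_crosstalk_hotspot_proteins=0, n_planted_hubs=3)
    paths, _ = sd.generate(cfg, tmp_path)
    catalog = build_catalog(_read_all_sites(cfg, paths))
    from collections import Counter

    counts = Counter(t for s in catalog for t in s.types)
    assert counts["phosphorylation"] > counts["ubiquitination"] >= counts["acetylation"]
    assert counts["phosphorylation"] > 3 * counts["acetylation"]
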