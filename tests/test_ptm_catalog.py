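"""Name canonicalisation, site deduplication, crosstalk detection and census."""

import logging

import pytest

from ptmatlas import ptm_catalog as pc
from ptmatlas.io_integration import ProteinRecord, PTMSiteRaw
from _oracles import brute_crosstalk_sites


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Phosphoserine", "phosphorylation"),
            ("Phosphothreonine", "phosphorylation"),
            ("PHOSPHOTYROSINE", "phosphorylation"),
            ("phosphorylation", "phosphorylation"),  # idempotent
            ("N6-acetyllysine", "acetylation"),
            ("N6,N6-dimethyllysine", "methylation"),
            ("N6,N6,N6-trimethyllysine", "methylation"),
            ("N-linked Glycosylation", "n-glycosylation"),
            ("O-GlcNAc", "o-glycosylation"),
            ("S-nitrosocysteine", "s-nitrosylation"),
            ("N6-succinyllysine", "succinylation"),
        ],
    )
    def test_default_mapping(self, raw, expected):
        assert pc.canonicalize_ptm_name(raw) == expected

    def test_unmapped_passes_through_lowercased(self, caplog):
        with caplog.at_level(logging.WARNING, logger="ptmatlas.catalog"):
            assert pc.canonicalize_ptm_name("Weirdmod-77") == "weirdmod-77"

    def test_empty_name_raises(self):
        with pytest.raises(ValueError):
            pc.canonicalize_ptm_name("  ")


class TestBuildCatalog:
    def test_same_type_two_sources_merge(self):
        raw = [
            PTMSiteRaw("P1", 15, "K", "Acetylation", "dbPTM"),
            PTMSiteRaw("P1", 15, "K", "N6-acetyllysine", "PSP"),
        ]
        (site,) = pc.build_catalog(raw)
        assert site.types == {"acetylation"}
        assert site.sources == {"dbPTM", "PSP"}

    def test_two_types_union_to_crosstalk(self):
        raw = [
            PTMSiteRaw("P1", 15, "K", "Acetylation", "dbPTM"),
            PTMSiteRaw("P1", 15, "K", "Ubiquitination", "dbPTM"),
        ]
        (site,) = pc.build_catalog(raw)
        assert site.types == {"acetylation", "ubiquitination"}
        assert site.is_crosstalk

    def test_position_beyond_sequence_dropped(self, caplog):
        proteome = {"P1": ProteinRecord("P1", "", "MKT")}
        raw = [PTMSiteRaw("P1", 999, "K", "Acetylation", "dbPTM")]
        with caplog.at_level(logging.INFO, logger="ptmatlas.catalog"):
            assert pc.build_catalog(raw, proteome) == []
        assert "dropped 1" in caplog.text

    def test_sequence_residue_wins_on_conflict(self, caplog):
        proteome = {"P1": ProteinRecord("P1", "", "MKT")}
        raw = [PTMSiteRaw("P1", 2, "R", "Acetylation", "dbPTM")]
        with caplog.at_level(logging.INFO, logger="ptmatlas.catalog"):
            (site,) = pc.build_catalog(raw, proteome)
        assert site.residue == "K"
        assert "residue conflicts" in caplog.text

    def test_idempotent_fixed_point(self, small_catalog):
        again = pc.build_catalog(small_catalog)
        assert [(s.accession, s.position, s.types, s.sources) for s in again] == [
            (s.accession, s.position, s.types, s.sources) for s in small_catalog
        ]


class TestCrosstalk:
    def test_selection_and_n_types(self, small_catalog):
        cts = pc.find_crosstalk_sites(small_catalog)
        assert [(c.site.accession, c.site.position, c.n_types) for c in cts] == [
            ("P1", 6, 2)
        ]

    def test_census_counts_and_conservation(self):
        sites = [
            pc.PTMSite("P1", i, "K", set(t), {"dbPTM"})
            for i, t in enumerate(
                [("acetylation", "ubiquitination"),
                 ("acetylation", "ubiquitination"),
                 ("acetylation", "methylation")],
                start=1,
            )
        ]
        combos, hist = pc.crosstalk_census(pc.find_crosstalk_sites(sites))
        as_dict = dict(zip(combos["combination"], combos["n_sites"]))
        assert as_dict == {"acetylation+ubiquitination": 2, "acetylation+methylation": 1}
        assert combos["n_sites"].sum() == 3
        assert dict(zip(hist["n_types"], hist["n_sites"])) == {2: 3}

    def test_empty_census(self):
        combos, hist = pc.crosstalk_census([])
        assert combos.empty and hist.empty

    def test_matches_groupby_oracle_on_random_tables(self, rng):
        type_pool = ["acetylation", "ubiquitination", "phosphorylation", "methylation"]
        for _ in range(300):
            rows = []
            for _ in range(int(rng.integers(1, 60))):
                rows.append((
                    f"P{int(rng.integers(1, 4))}",
                    int(rng.integers(1, 30)),
                    type_pool[int(rng.integers(len(type_pool)))],
                    ["dbPTM", "PSP", "neXtProt"][int(rng.integers(3))],
                ))
            raw = [PTMSiteRaw(a, p, "", t, s) for a, p, t, s in rows]
            catalog = pc.build_catalog(raw)
            got = sorted(
                (c.site.accession, c.site.position)
                for c in pc.find_crosstalk_sites(catalog)
            )
            expect_keys, expect_census = brute_crosstalk_sites(rows)
            assert got == expect_keys
            combos, _ = pc.crosstalk_census(pc.find_crosstalk_sites(catalog))
            assert dict(zip(combos["combination"], combos["n_sites"])) == expect_census


class TestSummaries:
    def test_hand_counted_protein(self):
        sites = [
            pc.PTMSite("P1", 1, "S", {"phosphorylation"}, {"dbPTM"}),
            pc.PTMSite("P1", 5, "S", {"phosphorylation"}, {"dbPTM"}),
            pc.PTMSite("P1", 9, "K", {"acetylation", "ubiquitination"}, {"dbPTM"}),
        ]
        (summary,), _ = pc.summarize_proteins(sites)
        assert summary.n_sites == 3
        assert summary.n_types == 3
        assert summary.n_crosstalk_sites == 1

    def test_global_means(self):
        sites = [pc.PTMSite("P1", i, "K", {"acetylation"}, {"dbPTM"}) for i in (1, 5)]
        sites += [pc.PTMSite("P2", i, "K", {"acetylation"}, {"dbPTM"}) for i in (1, 4, 8, 12)]
        _, glob = pc.summarize_proteins(sites)
        assert glob["mean_sites_per_protein"] == 3.0

    def test_site_counts_conserved(self, rng):
        sites = [
            pc.PTMSite(f"P{int(rng.integers(1, 6))}", int(p), "K",
                       {"acetylation"}, {"dbPTM"})
            for p in rng.choice(1000, size=80, replace=False)
        ]
        summaries, glob = pc.summarize_proteins(sites)
        assert sum(s.n_sites for s in summaries) == len(sites) == glob["n_sites"]


def test_catalog_frame_roundtrip(small_catalog):
    frame = pc.catalog_to_frame(small_catalog)
    back = pc.frame_to_catalog(frame)
    assert [(s.accession, s.position, s.types) for s in back] == [
        (s.accession, s.position, s.types) for s in small_catalog
    ]
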