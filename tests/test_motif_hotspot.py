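"""Motif windows, hotspot scanners, region stitching, coverage, profiles."""

import pytest

from ptmatlas import motif_hotspot as mh
from ptmatlas.ptm_catalog import PTMSite
from _oracles import (
    brute_crosstalk_hotspot_centers,
    brute_ptm_hotspot_centers,
    mask_stitch,
)


def _motif(acc, c, L=1000, flank=7):
    return mh.extract_motif(L, c, flank, acc)


class TestExtractMotif:
    def test_interior_window(self):
        m = mh.extract_motif(100, 50)
        assert (m.window_start, m.window_end) == (43, 57)
        assert not m.truncated_left and not m.truncated_right

    def test_short_protein_truncated_both(self):
        m = mh.extract_motif(10, 3)
        assert (m.window_start, m.window_end) == (1, 10)
        assert m.truncated_left and m.truncated_right

    def test_n_terminus(self):
        m = mh.extract_motif(100, 1)
        assert (m.window_start, m.window_end) == (1, 8)
        assert m.truncated_left and not m.truncated_right

    def test_center_out_of_range(self):
        with pytest.raises(ValueError):
            mh.extract_motif(10, 11)


class TestPTMScan:
    def test_worked_example_center_13(self):
        """Sites {10,12,13,15,16,20}: center 13 sees five co-occurring sites."""
        motifs = mh.scan_ptm_hotspots([10, 12, 13, 15, 16, 20], 100, k=5)
        assert 13 in [m.center for m in motifs]

    def test_sparse_sites_no_hotspot(self):
        assert mh.scan_ptm_hotspots([10, 30], 100, k=5) == []

    def test_k_zero_every_site_qualifies(self):
        motifs = mh.scan_ptm_hotspots([10, 30, 90], 100, k=0)
        assert [m.center for m in motifs] == [10, 30, 90]

    def test_matches_bruteforce(self, rng):
        for _ in range(300):
            L = int(rng.integers(20, 500))
            n = int(rng.integers(1, 50))
            sites = sorted(set(rng.integers(1, L + 1, size=n).tolist()))
            for k in (1, 3, 5):
                got = [m.center for m in mh.scan_ptm_hotspots(sites, L, k=k)]
                assert got == brute_ptm_hotspot_centers(sites, k)


class TestCrosstalkScan:
    def test_three_clustered_sites_qualify(self):
        motifs = mh.scan_crosstalk_hotspots([5, 9, 12], 100, k=3)
        assert 9 in [m.center for m in motifs]

    def test_dispersed_sites_never_qualify(self):
        assert mh.scan_crosstalk_hotspots([5, 40, 80], 100, k=3) == []

    def test_single_site_k1(self):
        motifs = mh.scan_crosstalk_hotspots([42], 100, k=1)
        assert [m.center for m in motifs] == [42]

    def test_exclude_center_is_stricter(self):
        inclusive = mh.scan_crosstalk_hotspots([5, 9, 12], 100, k=3)
        exclusive = mh.scan_crosstalk_hotspots([5, 9, 12], 100, k=3,
                                               include_center=False)
        assert len(exclusive) <= len(inclusive)
        assert exclusive == []

    def test_matches_bruteforce(self, rng):
        for _ in range(300):
            L = int(rng.integers(20, 500))
            sites = sorted(set(rng.integers(1, L + 1,
                                            size=int(rng.integers(1, 30))).tolist()))
            for k in (1, 3):
                for inc in (True, False):
                    got = [m.center for m in
                           mh.scan_crosstalk_hotspots(sites, L, k=k, include_center=inc)]
                    assert got == brute_crosstalk_hotspot_centers(
                        sites, k, include_center=inc)


class TestStitching:
    def test_overlapping_windows_merge(self):
        motifs = [_motif("P1", 13), _motif("P1", 15)]  # [6,20], [8,22]
        (region,) = mh.stitch_regions(motifs, "ptm")
        assert (region.start, region.end) == (6, 22)
        assert len(region) == 17
        assert region.n_qualifying_centers == 2

    def test_disjoint_windows_stay_separate(self):
        motifs = [_motif("P1", 8), _motif("P1", 27)]  # [1,15], [20,34]
        regions = mh.stitch_regions(motifs, "ptm")
        assert [(r.start, r.end) for r in regions] == [(1, 15), (20, 34)]

    def test_adjacent_windows_not_merged(self):
        # [6,20] and [21,35] share no position
        motifs = [_motif("P1", 13), _motif("P1", 28)]
        assert len(mh.stitch_regions(motifs, "ptm")) == 2

    def test_single_window_identity(self):
        (r,) = mh.stitch_regions([_motif("P1", 50)], "crosstalk")
        assert (r.start, r.end, r.kind) == (43, 57, "crosstalk")

    def test_matches_mask_oracle(self, rng):
        """Stitched regions cover exactly the mask union; since merely
        adjacent regions deliberately stay separate, interval identity is
        compared after collapsing adjacency."""
        from _oracles import merge_adjacent, regions_to_mask

        for _ in range(300):
            L = int(rng.integers(30, 400))
            centers = rng.integers(1, L + 1, size=int(rng.integers(1, 25)))
            motifs = [_motif("P1", int(c), L) for c in sorted(set(centers.tolist()))]
            regions = mh.stitch_regions(motifs, "ptm")
            windows = [(m.window_start, m.window_end) for m in motifs]
            expect_intervals, expect_cov = mask_stitch(windows, L)
            got_mask = regions_to_mask(regions, L)
            assert merge_adjacent([(r.start, r.end) for r in regions]) == expect_intervals
            assert got_mask.sum() / L == pytest.approx(expect_cov, abs=1e-12)
            assert abs(mh.coverage(regions, L) - expect_cov) < 1e-12


class TestCoverage:
    def test_worked_example(self):
        region = mh.HotspotRegion("P1", 6, 22, "ptm", 2)
        assert mh.coverage([region], 100) == pytest.approx(0.17)

    def test_no_regions_zero(self):
        assert mh.coverage([], 500) == 0.0

    def test_full_span_one(self):
        assert mh.coverage([mh.HotspotRegion("P1", 1, 80, "ptm", 1)], 80) == 1.0

    def test_overlapping_regions_rejected(self):
        regions = [
            mh.HotspotRegion("P1", 1, 10, "ptm", 1),
            mh.HotspotRegion("P1", 5, 20, "ptm", 1),
        ]
        with pytest.raises(ValueError):
            mh.coverage(regions, 100)

    def test_monotone_in_added_windows(self, rng):
        L = 300
        centers = sorted(set(rng.integers(1, L + 1, size=15).tolist()))
        prev = 0.0
        for i in range(1, len(centers) + 1):
            motifs = [_motif("P1", c, L) for c in centers[:i]]
            cov = mh.coverage(mh.stitch_regions(motifs, "ptm"), L)
            assert cov >= prev - 1e-12
            prev = cov


class TestPositionalProfile:
    def test_two_acetyl_sites_three_apart(self):
        catalog = [
            PTMSite("P1", 10, "K", {"acetylation"}, {"dbPTM"}),
            PTMSite("P1", 13, "K", {"acetylation"}, {"dbPTM"}),
        ]
        prof = mh.positional_profile(catalog, "acetylation", include_center=False)
        assert prof.fractions[-3] == 0.5
        assert prof.fractions[+3] == 0.5
        assert prof.n_total == 2

    def test_isolated_site_empty_profile(self):
        catalog = [PTMSite("P1", 10, "K", {"acetylation"}, {"dbPTM"})]
        prof = mh.positional_profile(catalog, "acetylation", include_center=False)
        assert prof.n_total == 0

    def test_include_center_counts_anchor(self):
        catalog = [PTMSite("P1", 10, "K", {"acetylation"}, {"dbPTM"})]
        prof = mh.positional_profile(catalog, "acetylation", include_center=True)
        assert prof.n_total == 1
        assert prof.fractions[0] == 1.0

    def test_combination_anchor_exact_by_default(self):
        catalog = [
            PTMSite("P1", 10, "K", {"acetylation", "ubiquitination"}, {"dbPTM"}),
            PTMSite("P1", 12, "K", {"acetylation", "ubiquitination", "sumoylation"},
                    {"dbPTM"}),
            PTMSite("P1", 14, "K", {"acetylation"}, {"dbPTM"}),
        ]
        exact = mh.positional_profile(
            catalog, ("acetylation", "ubiquitination"), include_center=False)
        superset = mh.positional_profile(
            catalog, ("acetylation", "ubiquitination"), include_center=False,
            exact_combination=False)
        assert exact.n_total == 2   # one anchor (pos 10) sees 12 and 14
        assert superset.n_total == 4  # anchors 10 and 12

    def test_fractions_normalised(self, rng):
        catalog = [
            PTMSite("P1", int(p), "K", {"acetylation"}, {"dbPTM"})
            for p in rng.choice(range(1, 100), size=30, replace=False)
        ]
        for mode in (True, False):
            prof = mh.positional_profile(catalog, "acetylation", include_center=mode)
            if prof.n_total:
                assert abs(sum(prof.fractions.values()) - 1.0) < 1e-9


class TestHotspotSummary:
    def _scan(self, acc, sites, L):
        return mh.scan_protein(sites, L)

    def test_cohort_partition_and_ratio(self):
        def site(acc, pos, ct=False):
            types = {"acetylation", "ubiquitination"} if ct else {"acetylation"}
            return PTMSite(acc, pos, "K", types, {"dbPTM"})

        # PA: dense plain sites -> PTM hotspot only
        pa = [site("PA", p) for p in range(10, 22, 2)]
        # PB: three clustered crosstalk sites only
        pb = [site("PB", p, ct=True) for p in (10, 12, 14)]
        scans = {
            "PA": mh.scan_protein(pa, 200),
            "PB": mh.scan_protein(pb, 200),
        }
        summaries, cohorts = mh.hotspot_summary(scans, {"PA": 200, "PB": 200})
        by_acc = {s.accession: s for s in summaries}
        assert by_acc["PA"].n_ptm_hotspot_centers > 0
        assert by_acc["PB"].n_ptm_hotspot_centers == 0
        assert by_acc["PB"].ratio is None  # crosstalk-only: ratio undefined
        both = cohorts["proteins_with_both"]
        union = (cohorts["proteins_with_ptm_hotspots"]
                 | cohorts["proteins_with_crosstalk_hotspots"])
        assert (len(both) + len(cohorts["proteins_ptm_only"])
                + len(cohorts["proteins_crosstalk_only"])) == len(union)
        assert cohorts["proteins_crosstalk_only"] == {"PB"}
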