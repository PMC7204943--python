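"""Variant notation parsing, motif mapping and MAV summaries."""

import pytest

from ptmatlas import variant_map as vm
from ptmatlas.io_integration import ParseError, ProteinRecord
from ptmatlas.motif_hotspot import HotspotRegion
from ptmatlas.ptm_catalog import PTMSite
from _oracles import brute_mav_pairs


class TestNotation:
    def test_three_letter_codes_mapped(self):
        assert vm.parse_variant_notation("p.Trp26Cys") == (26, "W", "C")

    def test_case_insensitive_codes(self):
        assert vm.parse_variant_notation("p.ALA5gly") == (5, "A", "G")

    def test_synonymous_rejected(self):
        with pytest.raises(ParseError):
            vm.parse_variant_notation("p.Ala5Ala")

    def test_garbage_rejected(self):
        with pytest.raises(ParseError):
            vm.parse_variant_notation("garbage")

    def test_unknown_code_rejected(self):
        with pytest.raises(ParseError, match="Xxx"):
            vm.parse_variant_notation("p.Xxx5Gly")


class TestClassificationLabels:
    @pytest.mark.parametrize(
        "label,expected",
        [("LP/P", "disease"), ("Pathogenic", "disease"),
         ("LB/B", "polymorphism"), ("benign", "polymorphism"),
         ("US", "unclassified"), ("whatever", "unclassified")],
    )
    def test_aliases(self, label, expected):
        assert vm.normalize_classification(label) == expected


def _site(acc, pos, ct=False):
    types = {"acetylation", "ubiquitination"} if ct else {"acetylation"}
    return PTMSite(acc, pos, "K", types, {"dbPTM"})


def _variant(acc, pos, cls="disease", ref="K", alt="R"):
    return vm.VariantRecord(acc, pos, ref, alt, cls)


class TestMapMavs:
    def test_offsets_and_boundary(self):
        catalog = [_site("P1", 15)]
        variants = [
            _variant("P1", 15), _variant("P1", 20), _variant("P1", 23)
        ]
        mavs, flags = vm.map_mavs(variants, catalog)
        offsets = {(m.variant.position, m.offset, m.at_site) for m in mavs}
        assert offsets == {(15, 0, True), (20, 5, False)}
        assert flags["is_mav"].tolist() == [True, True, False]

    def test_variant_near_two_sites_yields_two_pairs(self):
        catalog = [_site("P1", 10), _site("P1", 20)]
        mavs, flags = vm.map_mavs([_variant("P1", 15)], catalog)
        assert len(mavs) == 2
        assert int(flags["is_mav"].sum()) == 1  # one distinct variant

    def test_ref_mismatch_flagged_not_corrected(self, caplog):
        proteome = {"P1": ProteinRecord("P1", "", "MKTKA")}
        catalog = [_site("P1", 2)]
        mavs, flags = vm.map_mavs(
            [_variant("P1", 3, ref="W", alt="C")], catalog, proteome=proteome
        )
        assert not flags["ref_matches"].iloc[0]
        assert mavs[0].variant.ref_aa == "W"

    def test_matches_crossjoin_oracle(self, rng):
        for _ in range(300):
            L = int(rng.integers(30, 400))
            site_pos = sorted(set(rng.integers(1, L + 1,
                                               size=int(rng.integers(1, 30))).tolist()))
            var_pos = sorted(set(rng.integers(1, L + 1,
                                              size=int(rng.integers(1, 30))).tolist()))
            catalog = [_site("P1", p) for p in site_pos]
            variants = [_variant("P1", p) for p in var_pos]
            mavs, _ = vm.map_mavs(variants, catalog)
            got = sorted((m.variant.position, m.site_position) for m in mavs)
            assert got == brute_mav_pairs(var_pos, site_pos)


class TestSummaries:
    def _fixture(self):
        catalog = [_site("P1", 15, ct=True), _site("P1", 40), _site("P2", 8)]
        variants = [
            _variant("P1", 15, "disease"),
            _variant("P1", 18, "polymorphism"),
            _variant("P1", 44, "disease"),
            _variant("P2", 7, "unclassified"),
            _variant("P1", 100, "disease"),  # not a MAV
        ]
        mavs, flags = vm.map_mavs(variants, catalog)
        return catalog, variants, mavs, flags

    def test_class_counts_over_distinct_variants(self):
        _, _, mavs, flags = self._fixture()
        tables = vm.mav_summaries(mavs, flags)
        by_class = dict(zip(tables["by_class"]["class"],
                            tables["by_class"]["n_variants"]))
        assert by_class == {"disease": 2, "polymorphism": 1, "unclassified": 1}
        assert sum(by_class.values()) == int(flags["is_mav"].sum())

    def test_positional_histogram_conserves_pairs(self):
        _, _, mavs, flags = self._fixture()
        tables = vm.mav_summaries(mavs, flags)
        assert tables["positional"]["n_pairs"].sum() == len(mavs)

    def test_crosstalk_split_rows_sum_to_one(self):
        _, _, mavs, flags = self._fixture()
        tables = vm.mav_summaries(mavs, flags)
        split = tables["crosstalk_split"]
        assert ((split["frac_crosstalk"] + split["frac_non_crosstalk"]) - 1.0).abs().max() < 1e-9

    def test_hotspot_overlap_counts_interval_membership(self):
        _, _, mavs, flags = self._fixture()
        regions = {
            "P1": {"ptm": [HotspotRegion("P1", 6, 22, "ptm", 2)], "crosstalk": []}
        }
        tables = vm.mav_summaries(mavs, flags, hotspot_regions=regions,
                                  hotspot_report_threshold=2)
        row = tables["hotspot_overlap"].iloc[0]
        # variants at 15 and 18 fall inside [6,22]; 44 does not
        assert row["n_mavs_in_ptm_hotspots"] == 2
        assert row["n_mavs_in_crosstalk_hotspots"] == 0

    def test_disease_category_split(self):
        _, _, mavs, flags = self._fixture()
        tables = vm.mav_summaries(mavs, flags,
                                  categories={"P1": "CVD", "P2": "OD"})
        by_cat = dict(zip(tables["by_disease_category"]["category"],
                          tables["by_disease_category"]["n_variants"]))
        assert by_cat == {"CVD": 3, "OD": 1}
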