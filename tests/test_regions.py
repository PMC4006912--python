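"""Region merging, multi-breed consensus rules, CCR intersection."""

import random

import numpy as np
import pandas as pd
import pytest

from sweepscan import (CandidateRegion, ConsensusRegion, consensus,
                       intersect_ccr, merge_flags, pair_label)

from oracles import ccr_components_brute


def point_flags(chrom_positions):
    rows = [{"chrom": c, "center_pos": p, "start": p, "end": p}
            for c, p in chrom_positions]
    return pd.DataFrame(rows)


def region(chrom, start, end, method="FST", label="a~b"):
    return CandidateRegion(chrom=str(chrom), start=int(start), end=int(end),
                           method=method, label=label)


def cons(chrom, start, end, method="FST"):
    return ConsensusRegion(chrom=str(chrom), start=int(start), end=int(end),
                           method=method)


MB = 1_000_000


class TestMergeFlags:
    def test_gap_rule_splits_at_more_than_2mb(self):
        flags = point_flags([("1", 10 * MB), ("1", int(11.5 * MB)),
                             ("1", 14 * MB)])
        regs = merge_flags(flags, method="FST", label="x")
        assert [(r.start, r.end) for r in regs] == \
            [(10 * MB, int(11.5 * MB)), (14 * MB, 14 * MB)]

    def test_single_flag_gives_degenerate_region(self):
        regs = merge_flags(point_flags([("2", 5 * MB)]), method="OBSHTZ",
                           label="b")
        assert len(regs) == 1 and regs[0].start == regs[0].end == 5 * MB

    def test_exactly_2mb_gap_is_inclusive(self):
        regs = merge_flags(point_flags([("1", 10 * MB), ("1", 12 * MB)]))
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (10 * MB, 12 * MB)

    def test_merge_is_idempotent_on_point_flags(self, rng):
        positions = sorted(rng.integers(1, 100 * MB, size=40).tolist())
        flags = point_flags([("1", p) for p in positions])
        once = merge_flags(flags)
        region_rows = pd.DataFrame(
            [{"chrom": r.chrom, "center_pos": r.start,
              "start": r.start, "end": r.end} for r in once])
        twice = merge_flags(region_rows)
        assert [(r.start, r.end) for r in twice] == \
            [(r.start, r.end) for r in once]

    def test_window_extents_widen_the_region(self):
        flags = pd.DataFrame([
            {"chrom": "1", "center_pos": 10 * MB,
             "start": int(9.8 * MB), "end": int(10.2 * MB)},
            {"chrom": "1", "center_pos": 11 * MB,
             "start": int(10.8 * MB), "end": int(11.2 * MB)},
        ])
        regs = merge_flags(flags)
        assert (regs[0].start, regs[0].end) == (int(9.8 * MB), int(11.2 * MB))


class TestConsensusFst:
    def test_pairs_sharing_a_breed_rejected(self):
        regs = [region("1", 10 * MB, 11 * MB,
                       label=pair_label("MilkLacaune", "APM")),
                region("1", int(10.5 * MB), int(11.5 * MB),
                       label=pair_label("Comisana", "APM"))]
        assert consensus(regs, "FST") == []

    def test_disjoint_pairs_accepted_with_envelope_span(self):
        regs = [region("1", 10 * MB, 11 * MB,
                       label=pair_label("Churra", "Ojalada")),
                region("1", int(10.5 * MB), int(12.5 * MB),
                       label=pair_label("Chios", "Sakiz"))]
        out = consensus(regs, "FST")
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (10 * MB, int(12.5 * MB))
        assert set(out[0].labels) == {"Churra~Ojalada", "Chios~Sakiz"}

    def test_third_sharing_pair_rides_along(self):
        regs = [region("1", 10 * MB, 11 * MB, label="A~B"),
                region("1", 10 * MB, 11 * MB, label="C~D"),
                region("1", int(11.5 * MB), 13 * MB, label="A~C")]
        out = consensus(regs, "FST")
        assert len(out) == 1 and out[0].end == 13 * MB

    def test_malformed_pair_label_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            consensus([region("1", 1, 2, label="not_a_pair")], "FST")


class TestConsensusHet:
    DAIRY = {"Churra", "Chios", "MilkLacaune"}

    def test_one_dairy_plus_one_nondairy_rejected(self):
        regs = [region("1", 10 * MB, 11 * MB, "OBSHTZ", "Churra"),
                region("1", 10 * MB, 11 * MB, "OBSHTZ", "Ojalada")]
        assert consensus(regs, "HET", self.DAIRY) == []

    def test_two_dairy_accepted_nondairy_becomes_annotation(self):
        regs = [region("1", 10 * MB, 11 * MB, "OBSHTZ", "Churra"),
                region("1", int(10.2 * MB), int(11.4 * MB), "OBSHTZ", "Chios"),
                region("1", int(10.1 * MB), 11 * MB, "OBSHTZ", "Ojalada")]
        out = consensus(regs, "HET", self.DAIRY)
        assert len(out) == 1
        assert set(out[0].labels) == {"Churra", "Chios"}
        assert out[0].annotations == (("Ojalada", int(10.1 * MB), 11 * MB),)

    def test_output_independent_of_input_order(self, rng):
        regs = [region("2", 5 * MB, 6 * MB, "OBSHTZ", "Churra"),
                region("1", 10 * MB, 11 * MB, "OBSHTZ", "Churra"),
                region("1", int(11.5 * MB), 12 * MB, "OBSHTZ", "Chios"),
                region("2", 7 * MB, 8 * MB, "OBSHTZ", "MilkLacaune")]
        base = consensus(regs, "HET", self.DAIRY)
        shuffled = list(regs)
        random.Random(5).shuffle(shuffled)
        assert consensus(shuffled, "HET", self.DAIRY) == base


WORKED_EXAMPLE_FST = [("3", 152_680_000, 154_582_000),
                      ("3", 209_872_000, 215_814_000),
                      ("6", 30_367_000, 39_577_000),
                      ("13", 62_277_000, 65_811_000),
                      ("15", 72_774_000, 74_550_000),
                      ("22", 20_925_000, 23_157_000)]
WORKED_EXAMPLE_OBSHTZ = [("3", 153_950_000, 154_679_000),
                         ("3", 211_624_000, 215_403_000),
                         ("6", 34_576_000, 41_863_000),
                         ("13", 56_061_000, 63_781_000),
                         ("15", 72_843_000, 72_948_000),
                         ("22", 19_588_000, 20_991_000)]
WORKED_EXAMPLE_REGRESSION = [("6", 34_875_000, 38_875_000)]
WORKED_EXAMPLE_CCRS = [("3", 152_680_000, 154_679_000),
                       ("3", 209_872_000, 215_814_000),
                       ("6", 30_367_000, 41_863_000),
                       ("13", 56_061_000, 65_811_000),
                       ("15", 72_774_000, 74_550_000),
                       ("22", 19_588_000, 23_157_000)]


class TestIntersectCcr:
    def test_published_worked_example_yields_six_ccrs(self):
        """The thirteen published component intervals collapse into six
        convergence regions with the published envelopes, exactly one of
        which carries all three methods."""
        ccrs = intersect_ccr(
            [cons(*t) for t in WORKED_EXAMPLE_FST],
            [cons(*t, method="OBSHTZ") for t in WORKED_EXAMPLE_OBSHTZ],
            [cons(*t, method="REGRESSION") for t in WORKED_EXAMPLE_REGRESSION])
        assert len(ccrs) == 6
        spans = [(c.chrom, c.start, c.end) for c in ccrs]
        assert sorted(spans) == sorted(WORKED_EXAMPLE_CCRS)
        triple = [c for c in ccrs
                  if c.methods == {"FST", "OBSHTZ", "REGRESSION"}]
        assert len(triple) == 1
        assert (triple[0].chrom, triple[0].start, triple[0].end) == \
            ("6", 30_367_000, 41_863_000)

    def test_near_miss_is_not_a_ccr(self):
        """Proximity without bp overlap never makes a CCR (the 2-Mb rule
        does not apply at this stage)."""
        fst = [cons("3", 18_648_000, 19_360_000)]
        oh = [cons("3", 19_360_001, 20_000_000, method="OBSHTZ")]
        assert intersect_ccr(fst, oh) == []

    def test_single_bp_overlap_is_enough(self):
        fst = [cons("3", 18_648_000, 19_360_000)]
        oh = [cons("3", 19_360_000, 20_000_000, method="OBSHTZ")]
        ccrs = intersect_ccr(fst, oh)
        assert len(ccrs) == 1
        assert (ccrs[0].start, ccrs[0].end) == (18_648_000, 20_000_000)

    def test_het_regions_link_only_through_fst(self):
        # two ObsHtz regions overlap each other but only one touches FST
        fst = [cons("1", 10 * MB, 11 * MB)]
        oh = [cons("1", int(10.5 * MB), 12 * MB, method="OBSHTZ"),
              cons("1", int(11.5 * MB), 13 * MB, method="OBSHTZ")]
        ccrs = intersect_ccr(fst, oh)
        assert len(ccrs) == 1
        assert ccrs[0].end == 12 * MB  # second ObsHtz region not dragged in

    def test_matches_bruteforce_on_fuzzed_intervals(self, rng):
        for _ in range(200):
            def random_intervals(k):
                out = []
                for _ in range(k):
                    c = str(rng.integers(1, 4))
                    s = int(rng.integers(1, 50 * MB))
                    out.append((c, s, s + int(rng.integers(1, 5 * MB))))
                return out
            fst_iv = random_intervals(rng.integers(0, 6))
            oh_iv = random_intervals(rng.integers(0, 6))
            rg_iv = random_intervals(rng.integers(0, 3))
            got = intersect_ccr(
                [cons(*t) for t in fst_iv],
                [cons(*t, method="OBSHTZ") for t in oh_iv],
                [cons(*t, method="REGRESSION") for t in rg_iv])
            expected = ccr_components_brute(fst_iv, oh_iv + rg_iv)
            assert sorted((c.chrom, c.start, c.end) for c in got) == expected
            for c in got:  # type invariant
                assert "FST" in c.methods
                assert c.methods & {"OBSHTZ", "REGRESSION"}
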