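"""Histone-mark combinatorics, the filter pipeline and the summary tables."""

import numpy as np
import pytest

from regscan.enhancers import (CLASSES, EnhancerCall, PeakSet, apply_filters,
                               classify_stage, coverage_breakdown,
                               signature_matrix)
from regscan.errors import ValidationError
from regscan.intervals import ChromSizes, GenomeInterval, covered_bases, merge
from regscan.io.tracks import ConservationTrack
from regscan.params import Params
from regscan.synthetic import PlannedEnhancer, make_peaks

from conftest import bitmap, random_intervals


def iv(start, end, chrom="chrA"):
    return GenomeInterval(chrom, start, end)


def flat_track(size, value=1.0, chrom="chrA"):
    t = ConservationTrack(ChromSizes({chrom: size}))
    t.scores[chrom][:] = value
    return t


def peaksets(stage="S", k4me1=(), k4me3=(), k27ac=(), k27me3=()):
    out = [PeakSet("H3K4Me1", stage, list(k4me1))]
    for mark, regions in (("H3K4Me3", k4me3), ("H3K27Ac", k27ac),
                          ("H3K27Me3", k27me3)):
        if regions:
            out.append(PeakSet(mark, stage, list(regions)))
    return out


class TestClassifyStage:
    def test_promoter_mark_withholds_exclusion(self):
        (call,) = classify_stage(peaksets(k4me1=[iv(0, 1000)],
                                          k4me3=[iv(900, 1100)]))
        assert call.classes == {"putative"}

    def test_independent_memberships(self):
        (call,) = classify_stage(peaksets(
            k4me1=[iv(0, 1000)], k27ac=[iv(100, 200)], k27me3=[iv(800, 900)]))
        assert call.classes == {"putative", "promoter_excluded", "active",
                                "poised"}

    def test_missing_k4me1_rejected(self):
        with pytest.raises(ValidationError, match="H3K4Me1"):
            classify_stage([PeakSet("H3K27Ac", "S", [iv(0, 10)])])

    def test_mixed_stages_rejected(self):
        with pytest.raises(ValidationError):
            classify_stage([PeakSet("H3K4Me1", "S1", [iv(0, 10)]),
                            PeakSet("H3K27Ac", "S2", [iv(0, 10)])])

    def test_matches_per_region_overlap_oracle(self, rng):
        k4me1 = random_intervals(rng, 30)
        k4me3 = random_intervals(rng, 10)
        k27ac = random_intervals(rng, 10)
        k27me3 = random_intervals(rng, 10)
        calls = classify_stage(peaksets(k4me1=k4me1, k4me3=k4me3,
                                        k27ac=k27ac, k27me3=k27me3))
        size = 10_000
        bm3 = bitmap(k4me3, size)
        bmac = bitmap(k27ac, size)
        bmme3 = bitmap(k27me3, size)
        by_region = {(c.region.start, c.region.end): c.classes for c in calls}
        for r in sorted(k4me1, key=lambda i: (i.start, i.end)):
            expected = {"putative"}
            if not bm3[r.start:r.end].any():
                expected.add("promoter_excluded")
            if bmac[r.start:r.end].any():
                expected.add("active")
            if bmme3[r.start:r.end].any():
                expected.add("poised")
            assert by_region[(r.start, r.end)] == expected


class TestApplyFilters:
    def test_split_fragments_survive_and_inherit(self):
        (call,) = classify_stage(peaksets(k4me1=[iv(0, 1000)],
                                          k27ac=[iv(0, 50)]))
        got = apply_filters([call], [iv(400, 500)], flat_track(2000))
        assert [(c.region.start, c.region.end) for c in got] == \
            [(0, 400), (500, 1000)]
        assert all(c.classes == call.classes for c in got)
        assert all(c.parent_peak_id == call.parent_peak_id for c in got)

    def test_short_fragments_dropped(self):
        (call,) = classify_stage(peaksets(k4me1=[iv(0, 300)]))
        got = apply_filters([call], [iv(150, 250)], flat_track(2000))
        assert got == []  # fragments of 150 and 50 both below 200

    def test_unconserved_fragments_dropped(self):
        t = flat_track(2000, 0.3)
        (call,) = classify_stage(peaksets(k4me1=[iv(0, 1000)]))
        assert apply_filters([call], [], t) == []

    def test_matches_staged_brute_force(self, rng):
        size = 10_000
        vals = rng.uniform(0, 1, size)
        t = flat_track(size)
        t.scores["chrA"][:] = vals
        exons = random_intervals(rng, 15, max_len=300)
        k4me1 = random_intervals(rng, 25, max_len=800)
        calls = classify_stage(peaksets(k4me1=k4me1))
        params = Params()
        got = {(c.region.start, c.region.end) for c in
               apply_filters(calls, exons, t, params)}
        bm_ex = bitmap(exons, size)
        expected = set()
        for r in k4me1:
            # fragments = maximal runs of non-exonic bases inside r
            run = None
            for pos in range(r.start, r.end + 1):
                inside = pos < r.end and not bm_ex[pos]
                if inside and run is None:
                    run = pos
                elif not inside and run is not None:
                    if (pos - run >= params.enh_min_len
                            and vals[run:pos].mean() >= params.enh_cons_min):
                        expected.add((run, pos))
                    run = None
        assert got == expected

    def test_emitted_calls_respect_all_invariants(self, rng):
        size = 10_000
        t = flat_track(size)
        t.scores["chrA"][:] = rng.uniform(0.3, 1.0, size)
        exons = random_intervals(rng, 10)
        params = Params()
        calls = classify_stage(peaksets(k4me1=random_intervals(rng, 30)))
        bm_ex = bitmap(exons, size)
        for c in apply_filters(calls, exons, t, params):
            assert "putative" in c.classes
            assert len(c.region) >= params.enh_min_len
            assert c.mean_conservation >= params.enh_cons_min
            assert not bm_ex[c.region.start:c.region.end].any()


class TestPlanRoundTrip:
    def test_designed_classes_reproduced_end_to_end(self):
        plan = [
            PlannedEnhancer("chrA", 1000, 2000, "S",
                            frozenset({"putative", "promoter_excluded",
                                       "active"})),
            PlannedEnhancer("chrA", 3000, 3800, "S",
                            frozenset({"putative", "poised",
                                       "promoter_excluded"})),
            PlannedEnhancer("chrA", 5000, 5150, "S",
                            frozenset({"putative", "promoter_excluded"}),
                            fate="filtered_by_length"),
        ]
        peaks = make_peaks(plan)
        calls = classify_stage(peaks["S"])
        kept = apply_filters(calls, [], flat_track(10_000))
        got = {(c.region.start, c.region.end): c.classes for c in kept}
        assert got == {(1000, 2000): plan[0].classes,
                       (3000, 3800): plan[1].classes}

    def test_contradictory_plan_rejected(self):
        with pytest.raises(ValidationError, match="putative"):
            make_peaks([PlannedEnhancer("chrA", 0, 500, "S",
                                        frozenset({"active"}))])
        with pytest.raises(ValidationError, match="length"):
            make_peaks([PlannedEnhancer("chrA", 0, 500, "S",
                                        frozenset({"putative"}),
                                        fate="filtered_by_length")])


class TestSignatureMatrix:
    def test_counts_overlapping_calls(self):
        calls = [EnhancerCall(region=iv(100, 300), stage="S",
                              classes=frozenset({"putative"})),
                 EnhancerCall(region=iv(250, 400), stage="S",
                              classes=frozenset({"putative"}))]
        mat = signature_matrix([iv(200, 260)], {"S": calls})
        assert mat.loc["chrA:201-260", "S|putative"] == 2
        assert mat.loc["chrA:201-260", "S|active"] == 0

    def test_no_overlap_gives_zero_row(self):
        mat = signature_matrix([iv(5000, 5100)], {"S": []})
        assert (mat.values == 0).all()

    def test_matches_double_loop_oracle(self, rng):
        refs = merge(random_intervals(rng, 10))
        calls = {
            "S1": [EnhancerCall(region=r, stage="S1",
                                classes=frozenset({"putative", "active"}))
                   for r in random_intervals(rng, 20)],
            "S2": [EnhancerCall(region=r, stage="S2",
                                classes=frozenset({"putative", "poised"}))
                   for r in random_intervals(rng, 20)],
        }
        mat = signature_matrix(refs, calls)
        for r in refs:
            for stage in calls:
                for cls in CLASSES:
                    expected = sum(1 for c in calls[stage]
                                   if cls in c.classes
                                   and r.overlaps(c.region))
                    assert mat.loc[str(r), f"{stage}|{cls}"] == expected


class TestCoverageBreakdown:
    SIZES = ChromSizes({"chrA": 100_000})

    def test_single_mark_fraction(self):
        peaks = {"S": peaksets(k4me1=[iv(0, 10_000)])}
        df = coverage_breakdown(peaks, [], self.SIZES)
        k4 = df[df.combination == "H3K4Me1"].iloc[0]
        assert k4.bases == 10_000 and k4.fraction == pytest.approx(0.10)
        inter = df[df.combination == "H3K4Me1 & H3K27Ac"].iloc[0]
        assert inter.bases == 0

    def test_identical_sets_intersect_to_same_coverage(self):
        peaks = {"S": peaksets(k4me1=[iv(0, 5_000)], k27ac=[iv(0, 5_000)])}
        df = coverage_breakdown(peaks, [], self.SIZES).set_index("combination")
        assert df.loc["H3K4Me1 & H3K27Ac", "bases"] == \
            df.loc["H3K4Me1", "bases"]

    def test_matches_bitmap_coverage(self, rng):
        k4me1 = random_intervals(rng, 20)
        k27ac = random_intervals(rng, 20)
        exons = random_intervals(rng, 10)
        peaks = {"S": peaksets(k4me1=k4me1, k27ac=k27ac)}
        df = coverage_breakdown(peaks, exons,
                                ChromSizes({"chrA": 10_000})) \
            .set_index("combination")
        bm1, bmac, bmex = (bitmap(x, 10_000) for x in (k4me1, k27ac, exons))
        assert df.loc["H3K4Me1", "bases"] == bm1.sum()
        assert df.loc["H3K4Me1 & H3K27Ac", "bases"] == (bm1 & bmac).sum()
        assert df.loc["H3K4Me1", "bases_nonexonic"] == (bm1 & ~bmex).sum()
        assert df.loc["H3K4Me1 & H3K27Ac", "bases_nonexonic"] == \
            (bm1 & bmac & ~bmex).sum()
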