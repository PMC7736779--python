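"""Gap placement, repeat composition, pericentromeres, methylation."""

import numpy as np
import pytest

from asmdiff.core import GenomicInterval, InputError
from asmdiff.io import GapFlankAlignment, MarkerHit, MethylationSite
from asmdiff.params import GapPlacementParams, MethylationParams
from asmdiff.regions import (
    call_methylation,
    compare_pericentromeres,
    locate_pericentromere,
    place_gaps,
    repeat_composition,
)


def flank(gap_id, side, seq, start, end, score=6_000.0, alen=1_500):
    return GapFlankAlignment(gap_id, side, GenomicInterval(seq, start, end), score, alen)


class TestPlaceGaps:
    def test_qualifying_pair_placed(self):
        flanks = [
            flank("g1", "left", "chrA01", 100_000, 101_200, score=5_000, alen=1_200),
            flank("g1", "right", "chrA01", 143_500, 145_000, score=6_000, alen=1_500),
        ]
        placed, rejections, _ = place_gaps(flanks)
        assert [(g.gap_id, g.span.start, g.span.end) for g in placed] == [
            ("g1", 100_000, 145_000)
        ]
        assert rejections == {}

    @pytest.mark.parametrize(
        "right,reason",
        [
            (flank("g1", "right", "chrB02", 140_000, 141_500), "cross_sequence"),
            (flank("g1", "right", "chrA01", 140_000, 141_500, score=3_999), "score_or_length"),
            (flank("g1", "right", "chrA01", 140_000, 141_500, alen=900), "score_or_length"),
            (flank("g1", "right", "chrA01", 260_000, 261_500), "span"),
        ],
    )
    def test_rejection_reasons(self, right, reason):
        flanks = [flank("g1", "left", "chrA01", 100_000, 101_500), right]
        placed, rejections, _ = place_gaps(flanks)
        assert placed == [] and rejections == {"g1": reason}

    def test_single_side_rejected(self):
        placed, rejections, _ = place_gaps([flank("g1", "left", "c", 0, 1_500)])
        assert rejections == {"g1": "missing_side"}

    def test_minimal_span_wins_among_candidates(self):
        flanks = [
            flank("g1", "left", "c", 100_000, 101_500),
            flank("g1", "right", "c", 130_000, 131_500),
            flank("g1", "right", "c", 180_000, 181_500),
        ]
        placed, _, _ = place_gaps(flanks)
        assert placed[0].span.end == 131_500

    def test_placed_plus_rejected_partition_input(self, region_sim):
        placed, rejections, summary = place_gaps(region_sim.flanks)
        gap_ids = {f.gap_id for f in region_sim.flanks}
        assert {g.gap_id for g in placed} | set(rejections) == gap_ids
        assert {g.gap_id for g in placed}.isdisjoint(rejections)
        assert all(g.span_bases < GapPlacementParams().max_span for g in placed)
        assert summary["n_placed"] + summary["n_rejected"] == summary["n_input_gaps"]

    def test_planted_placeable_set_recovered(self, region_sim):
        placed, rejections, _ = place_gaps(region_sim.flanks)
        got = {g.gap_id: (g.span.seq_id, g.span.start, g.span.end) for g in placed}
        expected = {
            gid: (iv.seq_id, iv.start, iv.end)
            for gid, iv in region_sim.placeable_truth.items()
        }
        assert got == expected
        assert rejections == region_sim.unplaceable_reasons


class TestRepeatComposition:
    def test_half_masked(self):
        frac, per_class = repeat_composition(
            [GenomicInterval("c", 0, 1_000)],
            [(GenomicInterval("c", 0, 500), "LINE")],
        )
        assert frac == 0.5 and per_class == {"LINE": 500}

    def test_same_class_overlap_counted_once(self):
        frac, per_class = repeat_composition(
            [GenomicInterval("c", 0, 1_000)],
            [(GenomicInterval("c", 0, 300), "LINE"), (GenomicInterval("c", 200, 500), "LINE")],
        )
        assert per_class == {"LINE": 500} and frac == 0.5

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            span = 20_000
            regions = []
            pos = 0
            for _ in range(int(rng.integers(1, 5))):
                start = pos + int(rng.integers(0, 2_000))
                end = start + int(rng.integers(500, 4_000))
                if end > span:
                    break
                regions.append(GenomicInterval("c", start, end))
                pos = end + 10
            if not regions:
                continue
            repeats = []
            classes = ["A", "B", "C"]
            for _ in range(int(rng.integers(0, 15))):
                start = int(rng.integers(0, span - 500))
                repeats.append(
                    (GenomicInterval("c", start, start + int(rng.integers(100, 3_000))),
                     classes[int(rng.integers(0, 3))])
                )
            frac, per_class = repeat_composition(regions, repeats)

            in_region = np.zeros(span, dtype=bool)
            for r in regions:
                in_region[r.start : r.end] = True
            any_mask = np.zeros(span, dtype=bool)
            class_masks = {c: np.zeros(span, dtype=bool) for c in classes}
            for iv, cls in repeats:
                any_mask[iv.start : iv.end] = True
                class_masks[cls][iv.start : iv.end] = True
            expected_frac = (any_mask & in_region).sum() / in_region.sum()
            assert frac == pytest.approx(expected_frac)
            for cls in classes:
                expected = int((class_masks[cls] & in_region).sum())
                assert per_class.get(cls, 0) == expected


class TestPericentromere:
    def test_innermost_markers_delimit_region(self):
        markers = [
            MarkerHit("m1", "chr1", 5_000_000, "left"),
            MarkerHit("m2", "chr1", 5_200_000, "left"),
            MarkerHit("m3", "chr1", 7_900_000, "right"),
            MarkerHit("m4", "chr1", 8_400_000, "right"),
        ]
        (call,), flagged = locate_pericentromere(markers)
        assert (call.region.start, call.region.end) == (5_200_000, 7_900_000)
        assert call.size_bases == 2_700_000 and flagged == []

    def test_inverted_flanks_flagged(self):
        markers = [
            MarkerHit("m1", "chr1", 9_000_000, "left"),
            MarkerHit("m2", "chr1", 2_000_000, "right"),
        ]
        calls, flagged = locate_pericentromere(markers)
        assert calls == [] and flagged == ["chr1"]

    def test_fold_change_between_assemblies(self):
        a, _ = locate_pericentromere(
            [MarkerHit("m1", "c", 1_000_000, "left"), MarkerHit("m2", "c", 3_700_000, "right")]
        )
        b, _ = locate_pericentromere(
            [MarkerHit("m1", "c", 1_000_000, "left"), MarkerHit("m2", "c", 1_027_000, "right")]
        )
        comparison = compare_pericentromeres(a, b)
        assert comparison["c"]["size_fold"] == pytest.approx(100.0)

    def test_planted_boundaries_recovered(self, region_sim):
        calls, flagged = locate_pericentromere(region_sim.markers)
        assert flagged == []
        got = {c.chromosome: (c.region.start, c.region.end) for c in calls}
        expected = {
            chrom: (iv.start, iv.end) for chrom, iv in region_sim.centromere_truth.items()
        }
        assert got == expected


class TestCallMethylation:
    def _lengths(self):
        return {"c": 1_000_000}

    def test_thresholds(self):
        sites = [
            MethylationSite("c", 100, 5, 0.60),   # called
            MethylationSite("c", 200, 3, 0.60),   # depth below 4
            MethylationSite("c", 300, 10, 0.50),  # frequency not strictly above
        ]
        called, _ = call_methylation(sites, self._lengths())
        assert [s.position for s in called] == [100]

    def test_sweep_monotone_in_both_cutoffs(self):
        rng = np.random.default_rng(43)
        sites = [
            MethylationSite("c", int(p), int(rng.integers(0, 12)), float(rng.uniform(0, 1)))
            for p in sorted(rng.choice(900_000, size=300, replace=False))
        ]
        base, _ = call_methylation(sites, self._lengths())
        for depth, freq in [(6, 0.5), (4, 0.7), (8, 0.8)]:
            stricter, _ = call_methylation(
                sites, self._lengths(),
                MethylationParams(min_frequency=freq, min_depth=depth),
            )
            assert set(stricter) <= set(base)

    def test_window_track_fraction(self):
        sites = [
            MethylationSite("c", 10, 5, 0.9),
            MethylationSite("c", 20, 5, 0.1),
            MethylationSite("c", 150_000, 5, 0.9),
        ]
        _, track = call_methylation(sites, {"c": 200_000})
        assert track[0].fraction == pytest.approx(0.5)  # 1 of 2 assessed
        assert track[1].fraction == pytest.approx(1.0)

    def test_planted_truth_recovered(self, region_sim):
        called, _ = call_methylation(region_sim.methylation_sites, region_sim.chrom_lengths)
        got = {(s.seq_id, s.position) for s in called}
        expected = {k for k, v in region_sim.methylation_truth.items() if v}
        assert got == expected
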