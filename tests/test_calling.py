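import numpy as np
import pytest

from ckhs import CallingParams, CKHSRegion, call_ckhs, merge_regions, call_regions
from ckhs.calling import assign_ckhs_segments
from ckhs.segmentation import Segment, Segmentation, tguh_segment
from ckhs.simulate import SyntheticSpec, region_jaccard, simulate_screen


def seg(s, k=1, aa_start=1, aa_end=1, first=0, last=0):
    return Segment(k=k, s=s, aa_start=aa_start, aa_end=aa_end,
                   first_idx=first, last_idx=last)


def segmentation_of(segments):
    return Segmentation(boundaries=[], segments=list(segments))


class TestAssignment:
    def test_hand_traced_printed_mode(self):
        """Four unit segments s = [-5, -4, 0, 0.5]: the walk assigns the
        first two and stops (midpoints -2.375 then -2.0)."""
        segs = [seg(-5), seg(-4), seg(0), seg(0.5)]
        got = assign_ckhs_segments(segs, CallingParams(mean_mode="printed"))
        assert sorted(x.s for x in got) == [-5, -4]

    def test_weighted_equals_printed_for_unit_counts(self):
        segs = [seg(-5), seg(-4), seg(0), seg(0.5)]
        p = assign_ckhs_segments(segs, CallingParams(mean_mode="printed"))
        w = assign_ckhs_segments(segs, CallingParams(mean_mode="weighted"))
        assert sorted(x.s for x in p) == sorted(x.s for x in w)

    def test_single_segment_yields_no_regions(self):
        only = segmentation_of([seg(-3.0, k=10, aa_start=1, aa_end=100, last=9)])
        assert call_ckhs(only) == []

    def test_most_negative_segment_always_called(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            segs = [
                seg(float(rng.normal(-1, 1)), k=int(rng.integers(1, 50)),
                    aa_start=10 * i + 1, aa_end=10 * i + 10, first=i, last=i)
                for i in range(n)
            ]
            regions = call_ckhs(segmentation_of(segs))
            smin = min(segs, key=lambda g: g.s)
            assert any(
                r.start_aa <= smin.aa_start and r.end_aa >= smin.aa_end
                for r in regions
            )

    def test_weakest_segment_never_assigned(self):
        segs = [seg(-5.0), seg(-4.9), seg(-4.8), seg(-4.7)]
        got = assign_ckhs_segments(segs)
        assert max(x.s for x in got) < -4.7

    def test_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        segs = [
            seg(float(s), k=int(k), aa_start=int(a), aa_end=int(a) + 5)
            for s, k, a in zip(
                rng.normal(-1, 1, 6), rng.integers(1, 20, 6), np.arange(6) * 10 + 1
            )
        ]
        base = {(x.s, x.aa_start) for x in assign_ckhs_segments(segs)}
        for _ in range(5):
            perm = list(rng.permutation(len(segs)))
            got = {(x.s, x.aa_start) for x in assign_ckhs_segments([segs[i] for i in perm])}
            assert got == base

    def test_printed_mode_shift_non_invariance_with_unequal_k(self):
        """The verbatim count-normalized summaries are not shift-equivariant
        when segment sizes differ (motivates the weighted mode)."""
        segs = [seg(-2.0, k=10), seg(-1.5, k=1), seg(0.0, k=10), seg(0.1, k=1)]
        before = {x.s for x in assign_ckhs_segments(segs, CallingParams(mean_mode="printed"))}
        shifted = [seg(x.s + 5.0, k=x.k) for x in segs]
        after = {x.s - 5.0 for x in assign_ckhs_segments(shifted, CallingParams(mean_mode="printed"))}
        assert before != after


class TestMergeRegions:
    def test_adjacent_ckhs_segments_merge(self):
        regions = [CKHSRegion("G", 10, 20, -2.0, 5), CKHSRegion("G", 21, 35, -1.0, 10)]
        merged = merge_regions(regions, max_gap=0)
        assert len(merged) == 1
        assert (merged[0].start_aa, merged[0].end_aa) == (10, 35)
        # score is the mean over member points
        assert merged[0].score == pytest.approx((-2.0 * 5 - 1.0 * 10) / 15)

    def test_gap_within_limit_merges(self):
        regions = [CKHSRegion("G", 1, 12, -1, 6), CKHSRegion("G", 14, 25, -1, 6)]
        merged = merge_regions(regions, max_gap=2)
        assert [(r.start_aa, r.end_aa) for r in merged] == [(1, 25)]

    def test_gap_beyond_limit_kept_apart(self):
        regions = [CKHSRegion("G", 1, 12, -1, 6), CKHSRegion("G", 16, 25, -1, 6)]
        assert merge_regions(regions, max_gap=2) == regions

    def test_empty_input(self):
        assert merge_regions([]) == []

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            merge_regions([CKHSRegion("G", 1, 12, -1, 6), CKHSRegion("G", 10, 25, -1, 6)])

    def test_different_genes_never_merge(self):
        regions = [CKHSRegion("A", 1, 10, -1, 5), CKHSRegion("B", 11, 20, -1, 5)]
        assert len(merge_regions(regions, max_gap=100)) == 2


class TestFullPipelineCall:
    def test_output_regions_disjoint_sorted_within_protein(self):
        spec = SyntheticSpec(
            protein_length=900,
            planted_regions=[(100, 260, -1.4), (600, 780, -1.4)],
            seed=3,
        )
        prof, _ = simulate_screen(spec)
        regions = call_regions(prof)
        for a, b in zip(regions[:-1], regions[1:]):
            assert a.end_aa < b.start_aa
        for r in regions:
            assert 1 <= r.start_aa <= r.end_aa <= prof.protein_length

    def test_three_block_profile_recovers_three_regions(self):
        """A protein with sensitive N-terminal, middle and C-terminal
        blocks yields three called regions matching the planted truth."""
        spec = SyntheticSpec(
            protein_length=1200,
            planted_regions=[(20, 180, -1.2), (500, 680, -1.2), (1000, 1180, -1.2)],
            seed=7,
        )
        prof, truth = simulate_screen(spec)
        regions = call_regions(prof)
        assert len(regions) == 3
        for r, t in zip(regions, truth):
            assert region_jaccard(r, t) > 0.5

    def test_noiseless_two_level_recovery_is_exact(self):
        spec = SyntheticSpec(
            protein_length=200,
            planted_regions=[(51, 150, -2.0)],
            noise_sd=0.0,
            inactive_frac=0.0,
            outlier_frac=0.0,
            sgrna_density=1.0,
            seed=0,
        )
        prof, truth = simulate_screen(spec)
        regions = call_regions(prof)
        assert len(regions) == 1
        assert regions[0].score == pytest.approx(-2.2)
        assert region_jaccard(regions[0], truth[0]) > 0.9

    def test_empty_profile_no_calls(self, make_profile):
        assert call_regions(make_profile([])) == []
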