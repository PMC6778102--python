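from math import comb

import numpy as np
import pytest

from ckhs import (
    CKHSRegion,
    DomainAnnotation,
    aa_metrics,
    border_distance_enrichment,
    border_distances,
    evaluate,
    loess_baseline_call,
    permute_regions,
    ptm_density,
    region_domain_overlap,
)
from ckhs.evaluation import _random_placement, f1_score


def R(gene, start, end):
    return CKHSRegion(gene, start, end, -1.0, end - start + 1)


def D(protein, start, end, name="dom"):
    return DomainAnnotation(protein, name, start, end)


class TestAAMetrics:
    def test_half_overlap_hand_values(self):
        p, r, f1 = aa_metrics([R("G", 1, 50)], [D("G", 26, 75)], {"G": 100})
        assert (p, r, f1) == (0.5, 0.5, 0.5)

    def test_perfect_match(self):
        p, r, f1 = aa_metrics([R("G", 10, 40)], [D("G", 10, 40)], {"G": 100})
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_no_regions_convention(self):
        p, r, f1 = aa_metrics([], [D("G", 10, 40)], {"G": 100})
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_region_outside_protein_rejected(self):
        with pytest.raises(ValueError):
            aa_metrics([R("G", 90, 120)], [], {"G": 100})

    def test_protein_relabeling_invariant(self):
        regions = [R("A", 1, 30), R("B", 40, 60)]
        domains = [D("A", 20, 50), D("B", 50, 70)]
        lengths = {"A": 100, "B": 100}
        base = aa_metrics(regions, domains, lengths)
        swap = {"A": "B", "B": "A"}
        got = aa_metrics(
            [R(swap[r.gene], r.start_aa, r.end_aa) for r in regions],
            [D(swap[d.protein], d.start_aa, d.end_aa) for d in domains],
            lengths,
        )
        assert got == base

    def test_f1_formula_and_min_side_bound(self):
        for p in np.linspace(0, 1, 6):
            for r in np.linspace(0, 1, 6):
                f1 = f1_score(p, r)
                if p + r > 0:
                    assert f1 == pytest.approx(2 * p * r / (p + r))
                assert f1 <= 2 * min(p, r) + 1e-12


class TestRegionDomainOverlap:
    def test_printed_counts_reproduce_percentage(self):
        # 277 domains across proteins; regions overlap exactly 207 of them
        domains = [D(f"P{i}", 10, 60, f"d{i}") for i in range(277)]
        regions = [R(f"P{i}", 50, 80) for i in range(207)]
        out = region_domain_overlap(regions, domains)
        assert out["n_domains_identified"] == 207
        assert round(out["pct_domains_identified"], 1) == 74.7

    def test_disjoint_sets_zero(self):
        out = region_domain_overlap([R("G", 1, 10)], [D("G", 50, 60)])
        assert out["pct_regions_overlapping"] == 0.0
        assert out["pct_domains_identified"] == 0.0

    def test_hand_counted_toy(self):
        regions = [R("G", 1, 10), R("G", 30, 40), R("H", 5, 15)]
        domains = [D("G", 8, 20), D("G", 60, 70), D("H", 10, 25), D("H", 40, 50)]
        out = region_domain_overlap(regions, domains)
        assert round(out["pct_regions_overlapping"], 1) == 66.7  # 2 of 3
        assert round(out["pct_domains_identified"], 1) == 50.0  # 2 of 4


class TestBorderDistances:
    def test_exact_match_zero_distances(self):
        left, right, _ = border_distances([R("G", 40, 60)], [D("G", 40, 60)])
        assert left == [0] and right == [0]

    def test_sign_convention(self):
        # region 30-60, domain 40-60: left border 10 AA outside the domain
        left, right, _ = border_distances([R("G", 30, 60)], [D("G", 40, 60)])
        assert left == [10] and right == [0]
        # region starting inside the domain: negative left distance
        left, _, _ = border_distances([R("G", 50, 60)], [D("G", 40, 60)])
        assert left == [-10]

    def test_protein_without_domains_reported(self):
        _, _, skipped = border_distances([R("X", 1, 10)], [D("G", 1, 10)])
        assert skipped == ["X"]

    def test_enrichment_detects_matched_borders(self):
        lengths = {f"P{i}": 500 for i in range(12)}
        regions = [R(f"P{i}", 100, 200) for i in range(12)]
        domains = [D(f"P{i}", 95, 205) for i in range(12)]
        out = border_distance_enrichment(regions, domains, lengths, n_perm=50, seed=0)
        assert out["p_left"] < 0.01 and out["p_right"] < 0.01
        assert out["pct_left_within"] == 100.0


class TestPermuteRegions:
    def test_placement_preserves_counts_lengths_disjointness(self):
        rng = np.random.default_rng(0)
        regions = [R("G", 10, 60), R("G", 100, 140), R("H", 5, 25)]
        lengths = {"G": 300, "H": 50}
        for _ in range(50):
            placed = _random_placement(regions, lengths, rng)
            by_gene = {}
            for r in placed:
                by_gene.setdefault(r.gene, []).append(r)
                assert 1 <= r.start_aa <= r.end_aa <= lengths[r.gene]
            assert sorted(r.length for r in by_gene["G"]) == [41, 51]
            g = sorted(by_gene["G"], key=lambda r: r.start_aa)
            assert g[0].end_aa < g[1].start_aa

    def test_perfect_match_gives_minimal_p(self):
        # a region exactly matching its domain on a long protein: no random
        # placement reproduces F1 = 1, so p attains its lower bound
        regions = [R("G", 101, 400)]
        domains = [D("G", 101, 400)]
        null, p = permute_regions(regions, domains, {"G": 5000}, n_perm=99, seed=1)
        assert null.max() < 1.0
        assert p == pytest.approx(1.0 / 100.0)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permute_regions([R("G", 1, 10)], [], {"G": 100}, n_perm=0)

    def test_fixed_seed_reproducible(self):
        regions = [R("G", 10, 60)]
        domains = [D("G", 30, 90)]
        a = permute_regions(regions, domains, {"G": 200}, n_perm=50, seed=7)
        b = permute_regions(regions, domains, {"G": 200}, n_perm=50, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]


class TestPTMDensity:
    def test_all_sites_outside_matches_enumeration_oracle(self):
        # population 20 AA, 5 PTM AAs, 8 CKHS AAs, 0 inside: exact tail by
        # brute-force enumeration of the hypergeometric pmf
        regions = [R("G", 1, 8)]
        sites = {"G": [10, 12, 14, 16, 18]}
        res = ptm_density(regions, sites, {"G": 20})
        expected = comb(15, 8) / comb(20, 8)
        assert res.density_in == 0.0
        assert res.direction == "depletion"
        assert res.p_value == pytest.approx(expected)

    def test_zero_sites(self):
        res = ptm_density([R("G", 1, 10)], {}, {"G": 50})
        assert res.density_in == 0.0 and res.density_out == 0.0
        assert res.p_value == 1.0

    def test_uniform_sites_nonsignificant(self):
        rng = np.random.default_rng(2)
        lengths = {f"P{i}": 400 for i in range(5)}
        regions = [R(f"P{i}", 101, 220) for i in range(5)]
        ps = []
        for _ in range(20):
            sites = {g: list(np.flatnonzero(rng.random(400) < 0.08) + 1) for g in lengths}
            ps.append(ptm_density(regions, sites, lengths).p_depletion)
        assert np.mean(np.array(ps) < 0.05) < 0.3


class TestLoessBaseline:
    def test_flags_exactly_budget_aas(self, make_profile):
        rng = np.random.default_rng(3)
        prof = make_profile(rng.normal(-0.5, 0.5, 120), protein_length=120)
        for budget in [7, 30, 77]:
            regions = loess_baseline_call(prof, budget, merge_gap=0)
            assert sum(r.length for r in regions) == budget

    def test_constant_profile_left_anchored_run(self, make_profile):
        prof = make_profile([-1.0] * 60, protein_length=60)
        regions = loess_baseline_call(prof, 10)
        assert [(r.start_aa, r.end_aa) for r in regions] == [(1, 10)]

    def test_step_profile_recovers_negative_block(self, make_profile):
        scores = [-0.1] * 40 + [-3.0] * 30 + [-0.1] * 50
        prof = make_profile(scores, protein_length=120)
        regions = loess_baseline_call(prof, 30)
        assert len(regions) == 1
        # the 30 most negative smoothed AAs sit inside the planted block
        assert regions[0].start_aa >= 38 and regions[0].end_aa <= 73

    def test_budget_equal_length_spans_protein(self, make_profile):
        prof = make_profile([-1.0, -2.0, -0.5] * 10, protein_length=30)
        regions = loess_baseline_call(prof, 30)
        assert [(r.start_aa, r.end_aa) for r in regions] == [(1, 30)]

    def test_invalid_budget(self, make_profile):
        with pytest.raises(ValueError):
            loess_baseline_call(make_profile([-1.0] * 10), 0)


class TestEvaluateReport:
    def test_report_fields_consistent(self):
        regions = [R("G", 10, 60), R("H", 5, 30)]
        domains = [D("G", 40, 90), D("H", 100, 150)]
        rep = evaluate(regions, domains, {"G": 200, "H": 200})
        assert rep.n_regions == 2
        assert rep.n_identified_aas == 51 + 26
        assert 0 <= rep.precision <= 1 and 0 <= rep.recall <= 1
        assert rep.f1 == pytest.approx(f1_score(rep.precision, rep.recall))
        d = rep.to_dict()
        assert set(d) >= {"precision", "recall", "f1", "n_regions"}
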