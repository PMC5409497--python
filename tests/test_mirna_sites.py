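import numpy as np
import pytest

from utrhotspots import mirna_sites as mir
from utrhotspots.enrichment import EnrichmentProfile


def _site(utr, start, end, mirnas):
    return mir.TargetSite(utr, start, end, list(mirnas))


class TestFlagExpressedMirnas:
    def test_top_fifth_flagged(self):
        counts = [mir.MiRNAExpression(f"m{i}", float(i)) for i in range(1, 11)]
        mir.flag_expressed_mirnas(counts)
        flagged = {c.mirna_id for c in counts if c.expressed_flag}
        assert flagged == {"m9", "m10"}

    def test_ties_at_cutoff_all_included(self):
        counts = [mir.MiRNAExpression(f"m{i}", 7.0) for i in range(10)]
        mir.flag_expressed_mirnas(counts)
        assert all(c.expressed_flag for c in counts)

    def test_single_mirna_flagged(self):
        counts = [mir.MiRNAExpression("m0", 1.0)]
        mir.flag_expressed_mirnas(counts)
        assert counts[0].expressed_flag


class TestResolveOverlappingSites:
    def test_identical_seeds_merge_with_summed_expression(self):
        sites = [
            _site("u", 10, 17, [("miR-a", 100.0)]),
            _site("u", 10, 17, [("miR-b", 50.0)]),
        ]
        (out,) = mir.resolve_overlapping_sites(sites)
        assert out.total_expression == 150.0
        assert {m for m, _ in out.mirnas} == {"miR-a", "miR-b"}

    def test_highest_expressed_mirna_wins_overlap(self):
        sites = [
            _site("u", 10, 17, [("miR-a", 100.0)]),
            _site("u", 14, 21, [("miR-b", 50.0)]),
        ]
        (out,) = mir.resolve_overlapping_sites(sites)
        assert (out.seed_start, out.seed_end) == (10, 17)

    def test_disjoint_seeds_both_kept(self):
        sites = [
            _site("u", 10, 17, [("miR-a", 10.0)]),
            _site("u", 30, 37, [("miR-b", 5.0)]),
        ]
        assert len(mir.resolve_overlapping_sites(sites)) == 2

    def test_six_site_toy_table(self):
        """Chained resolution: merged seeds compete by their top miRNA."""
        sites = [
            _site("u", 10, 17, [("miR-1", 100.0)]),
            _site("u", 10, 17, [("miR-2", 50.0)]),
            _site("u", 14, 21, [("miR-3", 200.0)]),
            _site("u", 100, 107, [("miR-4", 30.0)]),
            _site("u", 200, 207, [("miR-5", 10.0)]),
            _site("u", 203, 210, [("miR-6", 5.0)]),
        ]
        out = mir.resolve_overlapping_sites(sites)
        got = [(s.seed_start, s.seed_end, s.total_expression) for s in out]
        assert got == [(14, 21, 200.0), (100, 107, 30.0), (200, 207, 10.0)]

    def test_output_mutually_non_overlapping(self, rng):
        sites = [
            _site("u", int(s), int(s) + 7, [(f"m{i}", float(rng.integers(1, 100)))])
            for i, s in enumerate(rng.integers(0, 200, size=40))
        ]
        out = mir.resolve_overlapping_sites(sites)
        for i, a in enumerate(out):
            for b in out[i + 1 :]:
                assert a.seed_end <= b.seed_start or b.seed_end <= a.seed_start


class TestAssignTiers:
    def _sites(self, n):
        return [_site("u", 10 * i, 10 * i + 7, [("m", float(i + 1))]) for i in range(n)]

    def test_nine_sites_split_evenly(self):
        sites = mir.assign_tiers(self._sites(9))
        tiers = [s.tier for s in sites]
        assert tiers.count(mir.TIER_LOW) == 3
        assert tiers.count(mir.TIER_MODERATE) == 3
        assert tiers.count(mir.TIER_HIGH) == 3

    def test_remainder_goes_to_lower_tiers(self):
        sites = mir.assign_tiers(self._sites(10))
        tiers = [s.tier for s in sites]
        assert tiers.count(mir.TIER_LOW) == 4
        assert tiers.count(mir.TIER_MODERATE) == 3
        assert tiers.count(mir.TIER_HIGH) == 3

    def test_highest_expression_is_high_tier(self):
        sites = mir.assign_tiers(self._sites(9))
        top = max(sites, key=lambda s: s.total_expression)
        assert top.tier == mir.TIER_HIGH

    def test_partition_is_total(self):
        sites = mir.assign_tiers(self._sites(14))
        assert all(
            s.tier in (mir.TIER_LOW, mir.TIER_MODERATE, mir.TIER_HIGH)
            for s in sites
        )

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError):
            mir.assign_tiers(self._sites(2))


class TestClassifyPosition:
    @pytest.mark.parametrize(
        "start,expected",
        [
            (7, mir.REGION_PROXIMAL),  # midpoint 10
            (147, mir.REGION_MEDIAL),  # midpoint 150
            (292, mir.REGION_DISTAL),  # midpoint ~295
        ],
    )
    def test_thirds(self, start, expected):
        site = _site("u", start, start + 7, [("m", 1.0)])
        assert mir.classify_position(site, 300) == expected


class TestRandomSiteSets:
    @pytest.fixture()
    def setup(self, rng):
        lengths = {f"u{i}": 100 + 10 * i for i in range(60)}
        sites = []
        for i in range(0, 60, 2):
            uid = f"u{i}"
            start = int(rng.integers(0, lengths[uid] - 7))
            sites.append(_site(uid, start, start + 7, [("m", 1.0)]))
        return sites, lengths

    def test_cardinality_conserved(self, setup, rng):
        sites, lengths = setup
        sets = mir.generate_random_site_sets(
            sites, lengths, rng, n_sets=5, n_length_groups=10
        )
        assert all(len(rs.sites) == len(sites) for rs in sets)

    def test_length_group_composition_conserved(self, setup, rng):
        sites, lengths = setup
        by_len = sorted({s.utr_id for s in sites}, key=lambda u: lengths[u])
        groups = np.array_split(np.array(by_len), 10)
        group_of = {u: g for g, grp in enumerate(groups) for u in grp}
        sets = mir.generate_random_site_sets(
            sites, lengths, rng, n_sets=5, n_length_groups=10
        )
        orig = sorted(group_of[s.utr_id] for s in sites)
        for rs in sets:
            assert sorted(group_of[s.utr_id] for s in rs.sites) == orig

    def test_relative_position_rescaled(self):
        # start 50 in a length-100 UTR moved to a length-200 UTR -> start 100
        lengths = {"a": 100, "b": 200}
        sites = [_site("a", 50, 57, [("m", 1.0)]), _site("b", 20, 27, [("m", 1.0)])]
        sets = mir.generate_random_site_sets(
            sites, lengths, rng=1, n_sets=50, n_length_groups=1
        )
        moved = [
            s
            for rs in sets
            for s in rs.sites
            if s.utr_id == "b" and s.seed_end - s.seed_start == 7
        ]
        starts = {s.seed_start for s in moved}
        assert 100 in starts  # the rescaled copy of the site at 50/100

    def test_same_length_target_keeps_coordinates(self):
        lengths = {"a": 150, "b": 150}
        sites = [_site("a", 40, 47, [("m", 1.0)])]
        sets = mir.generate_random_site_sets(
            sites, lengths, rng=3, n_sets=20, n_length_groups=1
        )
        assert all(rs.sites[0].seed_start == 40 for rs in sets)

    def test_too_few_utrs_for_groups_errors(self):
        lengths = {"a": 100}
        sites = [_site("a", 10, 17, [("m", 1.0)])]
        with pytest.raises(ValueError):
            mir.generate_random_site_sets(sites, lengths, rng=0, n_sets=2,
                                          n_length_groups=5)


class TestSiteMetaProfile:
    def test_plateau_over_seed_offsets(self):
        e = np.zeros(200)
        e[100:107] = 1.0
        profiles = {"u": EnrichmentProfile("u", "R", e)}
        sites = [_site("u", 100, 107, [("m", 1.0)])]
        prof = mir.site_meta_profile(profiles, sites, flank=10)
        np.testing.assert_allclose(prof[10:17], 1.0)  # offsets 0..6
        np.testing.assert_allclose(prof[:10], 0.0)
        np.testing.assert_allclose(prof[17:], 0.0)

    def test_all_zero_profiles_give_zero(self):
        profiles = {"u": EnrichmentProfile("u", "R", np.zeros(100))}
        sites = [_site("u", 50, 57, [("m", 1.0)])]
        assert mir.site_meta_profile(profiles, sites, flank=5).sum() == 0

    def test_single_site_equals_local_window(self, rng):
        e = rng.random(300)
        profiles = {"u": EnrichmentProfile("u", "R", e)}
        sites = [_site("u", 100, 107, [("m", 1.0)])]
        prof = mir.site_meta_profile(profiles, sites, flank=20)
        np.testing.assert_allclose(prof, e[80:121])

    def test_no_usable_sites_errors(self):
        with pytest.raises(ValueError):
            mir.site_meta_profile({}, [_site("u", 0, 7, [("m", 1.0)])], 5)


class TestEmpiricPvalue:
    def test_observed_above_all_random(self):
        p = mir.empiric_site_pvalue(10.0, np.arange(100, dtype=float) / 100)
        assert p == pytest.approx(1 / 101)

    def test_observed_below_all_random(self):
        p = mir.empiric_site_pvalue(-1.0, np.arange(100, dtype=float))
        assert p == 1.0

    def test_observed_at_median(self):
        p = mir.empiric_site_pvalue(49.5, np.arange(100, dtype=float))
        assert p == pytest.approx(51 / 101)

    def test_too_few_sets_errors(self):
        with pytest.raises(ValueError):
            mir.empiric_site_pvalue(1.0, np.arange(10, dtype=float))


class TestOverlapPermutationTest:
    def _random_sets(self, sites, n=25):
        return [mir.RandomSiteSet(i, sites) for i in range(n)]

    def test_clusters_exactly_on_sites(self):
        sites = [_site("u", 10, 17, [("m", 1.0)])]
        clusters = {"u": [(10, 17)]}
        res = mir.overlap_permutation_test(
            clusters, sites, self._random_sets(sites)
        )
        assert res["frac_clusters_on_sites"] == 1.0
        assert res["frac_sites_covered"] == 1.0

    def test_disjoint_clusters_and_sites(self):
        sites = [_site("u", 10, 17, [("m", 1.0)])]
        clusters = {"u": [(50, 60)]}
        res = mir.overlap_permutation_test(
            clusters, sites, self._random_sets(sites)
        )
        assert res["frac_clusters_on_sites"] == 0.0
        assert res["p_clusters"] == 1.0

    def test_single_nt_overlap_counts(self):
        sites = [_site("u", 10, 17, [("m", 1.0)])]
        clusters = {"u": [(16, 30)]}
        res = mir.overlap_permutation_test(
            clusters, sites, self._random_sets(sites)
        )
        assert res["frac_sites_covered"] == 1.0


class TestEnrichmentExpressionCorrelation:
    def test_proportional_gives_r_one(self):
        expr = np.array([1.0, 10.0, 100.0, 1000.0])
        r, p = mir.enrichment_expression_correlation(3 * expr, expr)
        assert r == pytest.approx(1.0)

    def test_zero_enrichment_sites_excluded(self):
        expr = np.array([1.0, 10.0, 100.0, 1000.0])
        enrich = np.array([0.0, 2.0, 20.0, 200.0])
        r, p = mir.enrichment_expression_correlation(enrich, expr)
        assert r == pytest.approx(1.0)

    def test_two_points_errors(self):
        with pytest.raises(ValueError):
            mir.enrichment_expression_correlation(
                np.array([1.0, 2.0]), np.array([1.0, 2.0])
            )
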