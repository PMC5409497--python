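import numpy as np
import pandas as pd
import pytest

from utrhotspots import hotspots as hot
from utrhotspots.mirna_sites import TargetSite


class TestPartitionWindows:
    @pytest.mark.parametrize(
        "length,n_windows,last_len",
        [(237, 5, 37), (100, 2, 50), (30, 1, 30)],
    )
    def test_tiling(self, length, n_windows, last_len):
        wins = hot.partition_windows(length, "u")
        assert len(wins) == n_windows
        assert wins[-1].end - wins[-1].start == last_len

    def test_tiling_covers_utr_disjointly(self):
        wins = hot.partition_windows(537, "u")
        assert wins[0].start == 0 and wins[-1].end == 537
        for a, b in zip(wins, wins[1:]):
            assert a.end == b.start
        assert sum(w.end - w.start for w in wins) == 537

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            hot.partition_windows(0, "u")


class TestAssignClusterCenters:
    def test_center_maps_to_containing_window(self):
        wins = hot.partition_windows(200, "u")
        hot.assign_cluster_centers(wins, {"A": [73]})
        assert wins[1].rbps == {"A"} and not wins[0].rbps

    def test_same_rbp_deduplicated_within_window(self):
        wins = hot.partition_windows(100, "u")
        hot.assign_cluster_centers(wins, {"AGO2": [10, 40]})
        assert wins[0].rbps == {"AGO2"} and wins[0].n_rbps == 1

    def test_half_open_window_boundary(self):
        wins = hot.partition_windows(100, "u")
        hot.assign_cluster_centers(wins, {"A": [49], "B": [50]})
        assert wins[0].rbps == {"A"} and wins[1].rbps == {"B"}

    def test_center_outside_utr_errors(self):
        wins = hot.partition_windows(100, "u")
        with pytest.raises(ValueError):
            hot.assign_cluster_centers(wins, {"A": [100]})


class TestAssignSitesToWindows:
    def _run(self, start, end):
        wins = hot.partition_windows(150, "u")
        site = TargetSite("u", start, end, [("m", 1.0)])
        _, assigned = hot.assign_sites_to_windows(wins, [site], {"m": True})
        return wins, assigned

    def test_six_of_seven_in_one_window_assigned(self):
        wins, assigned = self._run(44, 51)  # 6 nt in window 0
        assert len(assigned) == 1
        assert wins[0].mirna_overlap == hot.MIRNA_EXPRESSED

    def test_four_three_split_discarded(self):
        _, assigned = self._run(46, 53)
        assert assigned == []

    def test_five_two_split_discarded(self):
        # 5 nt is not > 5: discarded
        _, assigned = self._run(45, 52)
        assert assigned == []

    def test_unexpressed_mirna_labels_window(self):
        wins = hot.partition_windows(150, "u")
        site = TargetSite("u", 10, 17, [("m", 1.0)])
        hot.assign_sites_to_windows(wins, [site], {"m": False})
        assert wins[0].mirna_overlap == hot.MIRNA_UNEXPRESSED

    def test_assignment_is_unique(self):
        wins = hot.partition_windows(150, "u")
        site = TargetSite("u", 10, 20, [("m", 1.0)])  # 10-nt seed, window 0
        _, assigned = hot.assign_sites_to_windows(wins, [site], {"m": True})
        labeled = [w for w in wins if w.mirna_overlap != hot.MIRNA_NONE]
        assert len(labeled) == 1 and len(assigned) == 1


class TestCallHotspots:
    @pytest.mark.parametrize("n_rbps,expected", [(5, True), (4, False), (0, False)])
    def test_threshold(self, n_rbps, expected):
        w = hot.Window("u", 0, 0, 50, rbps={f"R{i}" for i in range(n_rbps)})
        assert hot.call_hotspots([w])[0] == expected


class TestUniformNull:
    def test_single_rbp_counts_conserved(self, rng):
        null = hot.simulate_uniform_null({"A": 7}, 20, rng, n_sims=50)
        assert (null.size_counts[:, 1] == 7).all()
        assert (null.size_counts[:, 0] == 13).all()

    def test_two_rbps_one_window_each_of_two(self, rng):
        # enumeration: 4 equiprobable placements, 2 collide -> E[size-2] = 0.5
        null = hot.simulate_uniform_null({"A": 1, "B": 1}, 2, rng, n_sims=4000)
        mean_size2 = null.size_counts[:, 2].mean()
        assert mean_size2 == pytest.approx(0.5, abs=0.05)

    def test_assignment_mass_conserved_every_sim(self, rng):
        counts = {"A": 5, "B": 3, "C": 8}
        null = hot.simulate_uniform_null(counts, 30, rng, n_sims=100)
        k = np.arange(null.size_counts.shape[1])
        total = (null.size_counts * k).sum(axis=1)
        assert (total == sum(counts.values())).all()

    def test_count_exceeding_windows_errors(self, rng):
        with pytest.raises(ValueError):
            hot.simulate_uniform_null({"A": 21}, 20, rng, n_sims=1)


class TestPositionalBinProfile:
    def test_uniform_items_flat(self, rng):
        lengths = {f"u{i}": 1000 for i in range(50)}
        items = {u: rng.integers(0, 1000, size=200) for u in lengths}
        prof = hot.positional_bin_profile(items, lengths)
        assert np.all(np.abs(prof - 1.0) < 0.25)

    def test_mass_in_last_bin(self):
        lengths = {"u": 500}
        items = {"u": np.arange(490, 500)}
        prof = hot.positional_bin_profile(items, lengths)
        assert prof[-1] == pytest.approx(50.0)
        assert prof[:-1].sum() == 0

    def test_empty_items_flagged_undefined(self):
        prof = hot.positional_bin_profile({}, {"u": 500})
        assert np.isnan(prof).all()


class TestWindowFeatures:
    def test_phylop_mean_ignores_undefined(self):
        w = hot.Window("u", 0, 0, 4)
        cons = np.array([1.0, 1.0, np.nan, 1.0])
        hot.window_feature_stats(w, conservation=cons)
        assert w.mean_phylop == pytest.approx(1.0)

    def test_phylop_all_undefined_flagged(self):
        w = hot.Window("u", 0, 0, 3)
        hot.window_feature_stats(w, conservation=np.full(3, np.nan))
        assert np.isnan(w.mean_phylop)

    def test_maf_sum_within_window(self):
        w = hot.Window("u", 0, 0, 50)
        hot.window_feature_stats(w, mafs=[(10, 0.1), (20, 0.2), (60, 0.4)])
        assert w.maf_sum == pytest.approx(0.3)

    def test_overlapping_are_counted(self):
        w = hot.Window("u", 0, 0, 10)
        hot.window_feature_stats(w, sequence="UAUUUAUUUA")
        assert w.are_count == 2

    def test_composition_sums_to_one(self):
        w = hot.Window("u", 0, 0, 8)
        hot.window_feature_stats(w, sequence="AUCGAUCG")
        assert sum(w.composition.values()) == pytest.approx(1.0)

    def test_dna_alphabet_accepted(self):
        assert hot.count_are("TATTTATTTA") == 2


class TestFeatureCorrelation:
    def test_feature_equal_to_rbp_count(self):
        df = pd.DataFrame(
            {
                "n_rbps": np.arange(20),
                "feat": np.arange(20, dtype=float),
                "mirna_overlap": ["none"] * 20,
            }
        )
        rho, p = hot.feature_vs_rbp_correlation(df, "feat")
        assert rho == pytest.approx(1.0)

    def test_independent_feature_near_zero(self, rng):
        df = pd.DataFrame(
            {
                "n_rbps": rng.integers(0, 10, size=3000),
                "feat": rng.normal(size=3000),
                "mirna_overlap": ["none"] * 3000,
            }
        )
        rho, p = hot.feature_vs_rbp_correlation(df, "feat")
        assert abs(rho) < 0.06

    def test_constant_feature_flagged(self):
        df = pd.DataFrame(
            {
                "n_rbps": np.arange(20),
                "feat": np.ones(20),
                "mirna_overlap": ["none"] * 20,
            }
        )
        rho, p = hot.feature_vs_rbp_correlation(df, "feat")
        assert np.isnan(rho)

    def test_small_stratum_errors(self):
        df = pd.DataFrame(
            {"n_rbps": [1], "feat": [1.0], "mirna_overlap": ["none"]}
        )
        with pytest.raises(ValueError):
            hot.feature_vs_rbp_correlation(df, "feat", stratum="none")


class TestBackgroundFilter:
    def _windows(self):
        wins = hot.partition_windows(200, "u")
        hot.assign_cluster_centers(
            wins, {f"R{i}": [10] for i in range(6)}
        )  # window 0 is a hotspot
        return wins

    def test_no_gfp_leaves_table_unchanged(self):
        wins = self._windows()
        kept, stats = hot.filter_background_windows(wins, {})
        assert len(kept) == len(wins)
        assert stats["frac_hotspots_flagged"] == 0.0

    def test_gfp_center_removes_hotspot_window(self):
        wins = self._windows()
        kept, stats = hot.filter_background_windows(wins, {"u": [5]})
        assert all(not (w.utr_id == "u" and w.index == 0) for w in kept)
        assert stats["frac_hotspots_flagged"] == 1.0
        assert stats["frac_gfp_in_hotspots"] == 1.0

    def test_all_windows_flagged_empties_table(self):
        wins = self._windows()
        centers = {"u": [w.start + 1 for w in wins]}
        kept, _ = hot.filter_background_windows(wins, centers)
        assert kept == []
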