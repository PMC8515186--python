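"""Zones, relative bins, and the two-population comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recland.caller import call_crossovers_population
from recland.core import MarkerMap
from recland.genmap import build_genetic_map, interval_stats
from recland.landscape import (
    GenomeLayout,
    assign_zone,
    bin_profile,
    chi2_two_zones,
    chi2_zone_proportions,
    compare_populations,
    markers_per_bin,
    terminal_bin_test,
    wilcoxon_compare,
    zone_shares,
    zone_summary,
)


@pytest.fixture
def layout():
    return GenomeLayout.default({"c1": 1_000_000, "c2": 2_000_000})


class TestLayout:
    def test_default_tiles_chromosomes(self, layout):
        lens = layout.chrom_lengths
        assert lens == {"c1": 1_000_000, "c2": 2_000_000}
        sub = layout.table[layout.table["chrom"] == "c1"]
        assert list(sub["zone"]) == ["Z1", "Z2", "Z3", "Z2", "Z1"]
        assert list(sub["arm"]) == ["S", "S", "C", "L", "L"]

    def test_gap_or_overlap_rejected(self, layout):
        broken = layout.table.copy()
        broken.loc[1, "start_bp"] += 5
        with pytest.raises(ValueError, match="tile"):
            GenomeLayout(broken)

    def test_zone_of_markers(self, layout):
        # c1 boundaries at 40k/380k/620k/960k
        assert assign_zone(layout, "c1", 500_000) == "Z3"
        assert assign_zone(layout, "c1", 10_000) == "Z1"

    def test_boundary_position_belongs_to_left_segment(self, layout):
        # midpoint exactly 1 bp left of the Z2->Z1 boundary (960001) is Z2
        assert assign_zone(layout, "c1", 960_000) == "Z2"
        assert assign_zone(layout, "c1", 960_001) == "Z1"

    def test_interval_assigned_by_midpoint(self, layout):
        assert assign_zone(layout, "c1", 950_000, 969_999) == "Z2"  # mid 959999

    def test_position_outside_bounds_rejected(self, layout):
        with pytest.raises(ValueError, match="outside"):
            layout.zone_of("c1", [0])
        with pytest.raises(ValueError, match="outside"):
            layout.zone_of("c1", [1_000_001])

    def test_round_trip_tsv(self, layout, tmp_path):
        path = tmp_path / "layout.tsv"
        layout.write(path)
        again = GenomeLayout.read(path)
        pd.testing.assert_frame_equal(again.table, layout.table)

    def test_uniform_markers_track_physical_shares(self, layout):
        pos = np.arange(1, 1_000_001, 1000)
        zones = layout.zone_of("c1", pos)
        shares = pd.Series(zones).value_counts(normalize=True)
        assert shares["Z2"] == pytest.approx(0.68, abs=0.01)
        assert shares["Z3"] == pytest.approx(0.24, abs=0.01)
        assert shares["Z1"] == pytest.approx(0.08, abs=0.01)


class TestChi2:
    def test_identical_populations_chi2_zero(self):
        s = pd.Series({"Z1": 50.0, "Z2": 40.0, "Z3": 10.0})
        out = chi2_zone_proportions(s, s)
        assert np.allclose(out["chi2"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_hand_computed_2x2(self):
        # [[60,40],[40,60]]: Pearson chi2 = 8.0, p ~ 0.00468
        chi2, p = chi2_two_zones(60, 40, 40, 60)
        assert chi2 == pytest.approx(8.0)
        assert p == pytest.approx(stats.chi2.sf(8.0, 1), rel=1e-6)
        assert p == pytest.approx(0.00468, abs=5e-5)

    def test_zero_marginal_undefined(self):
        a = pd.Series({"Z1": 0.0, "Z2": 0.0, "Z3": 0.0})
        b = pd.Series({"Z1": 10.0, "Z2": 5.0, "Z3": 0.0})
        out = chi2_zone_proportions(a, b).set_index("zone")
        assert np.isnan(out.loc["Z1", "p"])
        assert np.isnan(out.loc["Z3", "p"])  # zero column marginal


class TestWilcoxon:
    def test_identical_vectors_undefined(self):
        s, p = wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(p)

    def test_exact_doubling_example(self):
        a = [1, 2, 3, 4, 5, 6]
        b = [2, 4, 6, 8, 10, 12]
        s, p = wilcoxon_compare(a, b)
        assert p == pytest.approx(2 / 64)  # 0.03125 by exact enumeration

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        b = a + rng.normal(0.8, 1.0, size=50)
        s, p = wilcoxon_compare(a, b)
        assert 0 < p < 0.01

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 4000
        for _ in range(n_rep):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            _, p = wilcoxon_compare(a, b)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.06


class TestBins:
    def _one_interval_map(self, left, right, cm, length=1_000_000):
        iv = pd.DataFrame(
            {"chrom": ["c1"], "left_marker": "a", "right_marker": "b",
             "left_bp": [left], "right_bp": [right], "n_events": [1],
             "n_informative": [10], "r": [cm / 100], "cm": [cm]}
        )
        return build_genetic_map(iv)

    def test_interval_split_equally_across_two_bins(self):
        # spans exactly bins 1-2 of a 1 Mbp chromosome at 50 bins (20 kbp each)
        gmap = self._one_interval_map(1, 40_000, 10.0)
        prof = bin_profile(gmap, {"c1": 1_000_000})
        assert prof.loc[1, "cm"] == pytest.approx(5.0, rel=1e-4)
        assert prof.loc[2, "cm"] == pytest.approx(5.0, rel=1e-4)

    def test_midpoint_method_assigns_whole_interval(self):
        # midpoint 15000.5 falls in bin 1 (bins are 20 kbp wide)
        gmap = self._one_interval_map(1, 30_000, 10.0)
        prof = bin_profile(gmap, {"c1": 1_000_000}, method="midpoint")
        assert prof.loc[1, "cm"] == pytest.approx(10.0)

    def test_conservation(self, small_sim_config):
        from recland.simulate import simulate_f2

        gm, mm, _ = simulate_f2(small_sim_config)
        co = call_crossovers_population(gm, mm)
        gmap = build_genetic_map(interval_stats(co, gm, mm))
        lengths = {c.name: c.length_bp for c in small_sim_config.chromosomes}
        prof = bin_profile(gmap, lengths)
        assert prof["cm"].sum() == pytest.approx(gmap.genome_total_cm, rel=1e-9)

    def test_markers_per_bin_counts_everything(self):
        mm = MarkerMap(
            pd.DataFrame({"marker": [f"m{i}" for i in range(100)], "chrom": "c1",
                          "pos": np.linspace(1, 1_000_000, 100).astype(int)})
        )
        counts = markers_per_bin(mm, {"c1": 1_000_000})
        assert counts.sum() == 100


class TestZoneSummaryAndCompare:
    @pytest.fixture
    def distal_population(self):
        """Simulated population with all recombination in distal Z1."""
        from recland.simulate import ChromosomeSpec, Landscape, SimConfig, simulate_f2

        distal_only = Landscape(
            breaks=(0.0, 0.04, 0.96, 1.0), mass=(0.5, 0.0, 0.5)
        )
        chroms = tuple(
            ChromosomeSpec(f"c{i}", 50_000_000, 60.0, distal_only) for i in range(1, 4)
        )
        cfg = SimConfig(n_individuals=40, chromosomes=chroms, marker_density=10.0,
                        allele_error_rate=0.0, missing_rate=0.0, seed=17)
        gm, mm, _ = simulate_f2(cfg)
        co = call_crossovers_population(gm, mm)
        gmap = build_genetic_map(interval_stats(co, gm, mm))
        layout = GenomeLayout.default({c.name: c.length_bp for c in chroms})
        return gmap, mm, layout

    def test_distal_simulation_concentrates_in_z1(self, distal_population):
        gmap, mm, layout = distal_population
        zs = zone_summary(gmap, mm, layout).set_index("zone")
        assert zs.loc["Z1", "cm"] > 0.9 * gmap.genome_total_cm
        assert zs.loc["Z3", "cm"] == pytest.approx(0.0, abs=1e-9)

    def test_zone_cm_sums_to_genome_total(self, distal_population):
        gmap, mm, layout = distal_population
        zs = zone_summary(gmap, mm, layout)
        assert zs["cm"].sum() == pytest.approx(gmap.genome_total_cm, rel=1e-9)
        assert zs["n_markers"].sum() == mm.n_markers

    def test_empty_crossover_table_all_zones_zero(self, small_sim_config):
        from recland.simulate import simulate_f2

        gm, mm, _ = simulate_f2(small_sim_config)
        empty = pd.DataFrame(columns=["individual", "chrom", "left_bp", "right_bp", "score"])
        gmap = build_genetic_map(interval_stats(empty, gm, mm))
        layout = GenomeLayout.default({c.name: c.length_bp for c in small_sim_config.chromosomes})
        zs = zone_summary(gmap, mm, layout)
        assert zs["cm"].sum() == 0.0 and zs["co_score"].sum() == 0.0

    def test_zone_shares_sum_to_100(self, distal_population):
        gmap, mm, layout = distal_population
        zs = zone_summary(gmap, mm, layout)
        assert zone_shares(zs, "cm").sum() == pytest.approx(100.0)

    def test_compare_populations_conserves_and_reports(self, distal_population):
        gmap, mm, layout = distal_population
        report = compare_populations(gmap, gmap, mm, layout, n_bins=50)
        # identical populations: chi2 == 0, Wilcoxon undefined, bins identical
        assert np.allclose(report.zone_chi2["chi2"].dropna(), 0.0)
        assert np.isnan(report.wilcoxon_genome[1])
        pd.testing.assert_frame_equal(report.bins_a, report.bins_b)
        assert report.bins_a["cm"].sum() == pytest.approx(gmap.genome_total_cm, rel=1e-9)
        assert report.zone_a["cm"].sum() == pytest.approx(gmap.genome_total_cm, rel=1e-9)

    def test_terminal_bin_test_pairs_chromosome_arms(self, distal_population):
        gmap, mm, layout = distal_population
        prof = bin_profile(gmap, layout.chrom_lengths)
        shifted = prof.copy()
        chroms = [c for c in prof.columns if c != "cm"]
        # distinct positive bumps on the 6 terminal (chromosome x arm) values
        shifted.loc[[1, 50], chroms] += np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        s, p = terminal_bin_test(shifted, prof)
        # 6 arm pairs, all positive differences: exact two-sided p = 2/2^6
        assert p == pytest.approx(2 / 64)
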