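"""Generator behaviour: crossover process, genotype assembly, noise model."""

import numpy as np
import pytest
from scipy import stats

from recland.caller import call_crossovers_population
from recland.core import MISSING
from recland.simulate import (
    ChromosomeSpec,
    Landscape,
    SimConfig,
    apply_distal_shift,
    default_landscape,
    sample_gamete_crossovers,
    simulate_f2,
    total_true_crossovers,
    uniform_landscape,
)
from recland.validation import sensitivity, truth_intervals, well_separated


def _spec(cm=100.0, bp=100_000_000, landscape=None):
    return ChromosomeSpec("c1", bp, cm, landscape or uniform_landscape())


class TestGameteCrossovers:
    def test_zero_genetic_length_always_empty(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert sample_gamete_crossovers(_spec(cm=0.0), 1.0, rng).size == 0

    def test_zero_physical_length_empty(self):
        rng = np.random.default_rng(0)
        assert sample_gamete_crossovers(_spec(bp=0), 1.0, rng).size == 0

    def test_nonpositive_interference_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_gamete_crossovers(_spec(), 0.0, rng)
        with pytest.raises(ValueError):
            sample_gamete_crossovers(_spec(), -2.0, rng)

    def test_mean_count_matches_poisson(self):
        # L = 100 cM, nu = 1: mean CO count 1.00 within 3 SE at 10,000 gametes
        rng = np.random.default_rng(42)
        counts = [sample_gamete_crossovers(_spec(), 1.0, rng).size for _ in range(10_000)]
        assert abs(np.mean(counts) - 1.0) < 3.0 / np.sqrt(10_000)

    def test_positions_uniform_under_uniform_landscape(self):
        rng = np.random.default_rng(7)
        spec = _spec()
        pos = np.concatenate(
            [sample_gamete_crossovers(spec, 1.0, rng) for _ in range(5_000)]
        )
        ks = stats.kstest(pos / spec.length_bp, "uniform")
        assert ks.pvalue > 0.01

    def test_poisson_dispersion_at_nu_one(self):
        rng = np.random.default_rng(3)
        counts = np.array(
            [sample_gamete_crossovers(_spec(cm=200.0), 1.0, rng).size for _ in range(2_000)]
        )
        # index of dispersion ~ chi2(n-1)/(n-1) under a Poisson process
        d = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
        p = stats.chi2.sf(d, len(counts) - 1)
        assert 0.001 < p < 0.999

    def test_interference_underdisperses_counts(self):
        rng = np.random.default_rng(3)
        counts = np.array(
            [sample_gamete_crossovers(_spec(cm=300.0), 8.0, rng).size for _ in range(2_000)]
        )
        assert counts.var(ddof=1) < 0.8 * counts.mean()

    def test_positions_strictly_increasing_and_in_bounds(self):
        rng = np.random.default_rng(5)
        spec = _spec(cm=400.0, landscape=default_landscape())
        for _ in range(200):
            pos = sample_gamete_crossovers(spec, 1.0, rng)
            if pos.size:
                assert np.all(np.diff(pos) > 0)
                assert pos.min() > 0 and pos.max() < spec.length_bp


class TestLandscape:
    def test_quantile_inverts_cdf(self):
        ls = default_landscape()
        u = np.linspace(0.001, 0.999, 57)
        assert np.allclose(ls.cdf(ls.quantile(u)), u, atol=1e-12)

    def test_distal_shift_preserves_total_mass(self):
        ls = default_landscape()
        shifted = apply_distal_shift(ls, 0.10)
        assert np.isclose(np.sum(shifted.mass), np.sum(ls.mass))
        # terminal 2% gained exactly the mass removed from interstitial spans
        gained = (shifted.cdf(0.02) - ls.cdf(0.02)) + (ls.cdf(0.98) - shifted.cdf(0.98))
        inter = (ls.cdf(0.38) - ls.cdf(0.04)) + (ls.cdf(0.96) - ls.cdf(0.62))
        assert np.isclose(gained, 0.10 * inter, atol=1e-12)

    def test_invalid_landscape_rejected(self):
        with pytest.raises(ValueError):
            Landscape(breaks=(0.0, 0.5), mass=(1.0,))
        with pytest.raises(ValueError):
            Landscape(breaks=(0.0, 0.5, 1.0), mass=(1.0, -0.1))


class TestSimulateF2:
    def test_determinism(self, small_sim_config):
        a = simulate_f2(small_sim_config)
        b = simulate_f2(small_sim_config)
        assert np.array_equal(a[0].calls, b[0].calls)
        assert all(
            np.array_equal(x.positions, y.positions) and x.individual == y.individual
            for x, y in zip(a[2], b[2])
        )

    def test_zero_length_gives_nonrecombinant_constant_genotypes(self):
        chroms = (ChromosomeSpec("c1", 1_000_000, 0.0, uniform_landscape()),)
        gm, mm, truths = simulate_f2(
            SimConfig(n_individuals=20, chromosomes=chroms, marker_density=20.0,
                      allele_error_rate=0.0, missing_rate=0.0, seed=1)
        )
        assert total_true_crossovers(truths) == 0
        assert (gm.calls == gm.calls[0]).all()

    def test_missing_fraction_matches_rate(self, small_sim_config):
        from dataclasses import replace

        cfg = replace(small_sim_config, missing_rate=0.05, seed=2)
        gm, _, _ = simulate_f2(cfg)
        frac = (gm.calls == MISSING).mean()
        n = gm.calls.size
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_single_marker_genotypes_segregate_1_2_1(self):
        chroms = (ChromosomeSpec("c1", 1_000_000, 0.0, uniform_landscape()),)
        gm, _, _ = simulate_f2(
            SimConfig(n_individuals=2_000, chromosomes=chroms, marker_density=2.0,
                      allele_error_rate=0.0, missing_rate=0.0, seed=9)
        )
        obs = [(gm.calls[0] == c).sum() for c in (0, 1, 2)]
        p = stats.chisquare(obs, f_exp=[500, 1000, 500]).pvalue
        assert p > 0.001

    def test_visible_transitions_near_two_l(self):
        # each F2 individual carries two meioses: E[transitions] = 2 L / 100
        chroms = (ChromosomeSpec("c1", 50_000_000, 50.0, uniform_landscape()),)
        gm, _, _ = simulate_f2(
            SimConfig(n_individuals=1_000, chromosomes=chroms, marker_density=4.0,
                      allele_error_rate=0.0, missing_rate=0.0, seed=4)
        )
        per_ind = (gm.calls[:-1] != gm.calls[1:]).sum(axis=0)
        se = per_ind.std(ddof=1) / np.sqrt(len(per_ind))
        assert abs(per_ind.mean() - 1.0) < 3 * se

    def test_marker_outside_bounds_rejected(self, small_sim_config):
        import pandas as pd
        from dataclasses import replace

        from recland.core import MarkerMap

        bad = MarkerMap(pd.DataFrame({"marker": ["m1"], "chrom": ["c1"], "pos": [99_000_000]}))
        with pytest.raises(ValueError, match="outside chromosome"):
            simulate_f2(replace(small_sim_config, markers=bad))

    def test_invalid_rates_rejected(self, small_sim_config):
        from dataclasses import replace

        with pytest.raises(ValueError):
            replace(small_sim_config, allele_error_rate=1.5)
        with pytest.raises(ValueError):
            replace(small_sim_config, missing_rate=-0.1)
        with pytest.raises(ValueError):
            replace(small_sim_config, interference_shape=0.0)

    def test_caller_recovers_well_separated_truth(self, small_sim_config):
        from dataclasses import replace

        cfg = replace(small_sim_config, n_individuals=200, seed=21)
        gm, mm, truths = simulate_f2(cfg)
        co = call_crossovers_population(gm, mm)
        ti = truth_intervals(truths, mm)
        ws = well_separated(ti, min_co_gap=4, min_end_gap=3)
        sens, hits, total = sensitivity(co, ws, mm)
        assert total > 100
        assert sens == 1.0
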