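"""Weir-Cockerham FST, Tajima's D, and their empirical significance rules."""

import math

import msprime
import numpy as np
import pandas as pd
import pytest

from teadapt.freq_stats import (concordance_filter, fixed_te_tajima_flags,
                                fst_significance, pooled_pseudocounts, tajima_d,
                                tajima_quantile_cuts, tajima_windows, wc_fst)

from conftest import make_te


def wc84_oracle(n1, d1, n2, d2):
    """Independent WC84 evaluation: general multi-allele component sums.

    Follows the per-allele formulation (summing a and b over both alleles of
    the biallelic locus) rather than the single-allele shortcut used in the
    implementation.
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = 0.0
    for derived in (True, False):
        p1 = (d1 if derived else n1 - d1) / n1
        p2 = (d2 if derived else n2 - d2) / n2
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a_sum += (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b_sum += (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return a_sum / (a_sum + b_sum) if (a_sum + b_sum) != 0 else math.nan


class TestWcFst:
    def test_equal_frequencies_give_nonpositive_theta(self):
        res = wc_fst(20, 10, 20, 10)
        assert res.a <= 0 and res.theta <= 0

    def test_complete_differentiation(self):
        res = wc_fst(20, 20, 20, 0)
        assert res.theta == pytest.approx(wc84_oracle(20, 20, 20, 0))
        assert res.theta == pytest.approx(1.0)
        assert res.direction == "pop1"

    def test_monomorphic_undefined(self):
        res = wc_fst(20, 20, 20, 20)
        assert not res.defined and math.isnan(res.theta)

    def test_matches_independent_formulation(self, rng):
        """Agreement with the per-allele component sums on 1,000 random counts."""
        for _ in range(1000):
            n1, n2 = rng.integers(2, 80, size=2)
            d1, d2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            if d1 == 0 and d2 == 0 or d1 == n1 and d2 == n2:
                continue
            mine = wc_fst(int(n1), int(d1), int(n2), int(d2)).theta
            assert mine == pytest.approx(wc84_oracle(n1, d1, n2, d2), abs=1e-10)

    def test_pooled_pseudocounts_capped(self):
        assert pooled_pseudocounts(0.5, 30, 40) == (40, 20)   # read-limited
        assert pooled_pseudocounts(0.5, 10, 200) == (20, 10)  # pool-size-limited


class TestFstSignificance:
    def test_null_median_not_significant(self, rng):
        null = {"AF_high": rng.uniform(0, 0.2, 500), "AF_low": rng.uniform(0, 0.2, 500)}
        med = float(np.median(null["AF_high"]))
        flags = fst_significance({"te": med}, null, {"te": 0.5})
        assert flags["te"] is False

    def test_above_all_null_values_significant(self, rng):
        null = {"AF_high": rng.uniform(0, 0.2, 500), "AF_low": rng.uniform(0, 0.2, 500)}
        assert fst_significance({"te": 0.9}, null, {"te": 0.5})["te"] is True

    def test_neutral_self_test_rate(self, rng):
        """~5% of the null SNPs exceed their own 95th percentile."""
        values = rng.normal(0.05, 0.03, size=2000)
        null = {"AF_high": values, "AF_low": values}
        flags = fst_significance(
            {f"s{i}": v for i, v in enumerate(values)}, null,
            {f"s{i}": 0.5 for i in range(2000)},
        )
        rate = np.mean(list(flags.values()))
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * se

    def test_missing_african_frequency_skipped(self, caplog):
        null = {"AF_high": [0.1] * 200, "AF_low": [0.1] * 200}
        flags = fst_significance({"te": 0.5}, null, {})
        assert "te" not in flags
        assert "skipped" in caplog.text


class TestConcordance:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["te_id", "pair", "significant", "high_side"])

    def test_two_concordant_pairs_kept(self):
        rec = self._records([("te", "EU", True, "high"), ("te", "NA", True, "high")])
        assert concordance_filter(rec) == {"te"}

    def test_opposite_sides_dropped(self):
        rec = self._records([("te", "EU", True, "high"), ("te", "NA", True, "low")])
        assert concordance_filter(rec) == set()

    def test_single_significant_pair_dropped(self):
        rec = self._records([("te", "EU", True, "high"), ("te", "NA", False, "high")])
        assert concordance_filter(rec) == set()


class TestTajimaD:
    def test_no_segregating_sites(self):
        D, S, pi = tajima_d(np.zeros((6, 10), dtype=int))
        assert math.isnan(D) and S == 0

    def test_hand_computed_singletons(self):
        """n = 4 with three singleton sites, evaluated constant by constant."""
        alleles = np.zeros((4, 3), dtype=int)
        alleles[0, 0] = alleles[1, 1] = alleles[2, 2] = 1
        D, S, pi = tajima_d(alleles)
        assert S == 3 and pi == pytest.approx(1.5)
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1, b2 = 5 / 9, 2 * (16 + 4 + 3) / (9 * 4 * 3)
        c1 = b1 - 1 / a1
        c2 = b2 - 6 / (a1 * 4) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (1.5 - 3 / a1) / math.sqrt(e1 * 3 + e2 * 3 * 2)
        assert D == pytest.approx(expected, rel=1e-12)

    def test_intermediate_frequencies_give_positive_d(self):
        alleles = np.zeros((4, 6), dtype=int)
        alleles[:2] = 1  # every site at frequency 1/2
        D, S, pi = tajima_d(alleles)
        assert D > 0

    def test_agrees_with_tskit_on_coalescent_simulations(self):
        """Oracle: tskit's Tajima's D on msprime neutral simulations."""
        for seed in range(1, 21):
            ts = msprime.sim_ancestry(
                samples=10, ploidy=1, sequence_length=5e4,
                recombination_rate=1e-8, population_size=1e4, random_seed=seed,
            )
            ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed)
            if ts.num_sites == 0:
                continue
            G = ts.genotype_matrix().T  # haplotypes x sites
            G = np.minimum(G, 1)
            D, S, pi = tajima_d(G)
            assert D == pytest.approx(float(ts.Tajimas_D()), abs=1e-8)

    def test_near_zero_mean_under_neutrality(self):
        """E[D] is approximately 0 for neutral coalescent samples."""
        values = []
        for seed in range(100, 200):
            ts = msprime.sim_ancestry(samples=15, ploidy=1, sequence_length=2e4,
                                      population_size=1e4, random_seed=seed)
            ts = msprime.sim_mutations(ts, rate=2e-8, random_seed=seed)
            if ts.num_sites < 3:
                continue
            values.append(tajima_d(np.minimum(ts.genotype_matrix().T, 1))[0])
        assert abs(np.mean(values)) < 0.3


class TestTajimaWindows:
    def _windows(self):
        return pd.DataFrame({
            "chrom": ["2L", "2L", "X"],
            "start": [0, 10_000, 0],
            "end": [500, 10_500, 500],
            "S": [5, 5, 5], "pi": [1, 1, 1],
            "D": [-1.70, -1.70, -1.70],
        })

    def test_autosome_cut_flags_overlapping_te(self):
        te = make_te(te_id="fx", chrom="2L", start=100, end=400)
        assert fixed_te_tajima_flags(self._windows(), [te]) == {"fx"}

    def test_x_chromosome_uses_stricter_cut(self):
        te = make_te(te_id="fx", chrom="X", start=100, end=400)
        assert fixed_te_tajima_flags(self._windows(), [te]) == set()

    def test_distant_window_not_counted(self):
        te = make_te(te_id="fx", chrom="2L", start=12_500, end=13_000)  # 2 kb away
        assert fixed_te_tajima_flags(self._windows(), [te]) == set()

    def test_windowing_and_quantiles(self, rng):
        alleles = rng.integers(0, 2, size=(10, 60)).astype(np.int8)
        positions = np.sort(rng.choice(3_000, size=60, replace=False))
        win = tajima_windows(alleles, positions, "2L", chrom_length=3_000)
        assert len(win) == 6
        assert (win["end"] - win["start"]).max() == 500
        cuts = tajima_quantile_cuts(win)
        assert "autosome" in cuts
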