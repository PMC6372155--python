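"""The forward Wright-Fisher generator and the observation emitters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teadapt.sweep_scan import HaplotypeMatrix, h12_window, ihs, nsl
from teadapt.synthetic_data import (SimConfig, SweepNotEstablishedError,
                                    emit_te_observations, simulate_population,
                                    simulate_te_panel, write_vcf)

SMALL = dict(n_haplotypes=100, n_sites=60, sequence_length=10_000,
             focal_position=5_000, burnin_generations=100)


class TestSimulator:
    def test_seed_determinism(self):
        cfg = SimConfig(sweep_kind="hard", selection_coefficient=0.1, seed=7, **SMALL)
        hap1, truth1 = simulate_population(cfg)
        hap2, truth2 = simulate_population(cfg)
        assert np.array_equal(hap1.alleles, hap2.alleles)
        assert np.array_equal(hap1.positions, hap2.positions)
        assert truth1.sweep_position == truth2.sweep_position

    def test_neutral_focal_frequency_is_a_martingale(self):
        """Mean final frequency over 200 seeded replicates stays at the start."""
        finals = []
        for seed in range(200):
            cfg = SimConfig(sweep_kind="none", init_focal_frequency=0.5, seed=seed, **SMALL)
            hap, truth = simulate_population(cfg)
            finals.append(hap.derived_frequency(truth.sweep_site))
        se = np.std(finals) / math.sqrt(len(finals))
        assert abs(np.mean(finals) - 0.5) < 3 * se

    def test_hard_sweep_raises_focal_frequency(self):
        """Selection drives the focal allele up, as the one-locus WF recursion
        p' = p(1+s)/(1+ps) predicts; every established replicate ends above
        its 1/N starting frequency."""
        s, n = 0.1, SMALL["n_haplotypes"]
        p = 1.0 / n
        for _ in range(500):
            p = p * (1 + s) / (1 + p * s)
        assert p > 0.95  # the deterministic recursion reaches high frequency
        above = 0
        for seed in range(100):
            cfg = SimConfig(sweep_kind="hard", selection_coefficient=s,
                            target_frequency=0.5, seed=seed, **SMALL)
            hap, truth = simulate_population(cfg)
            above += hap.derived_frequency(truth.sweep_site) > 1.0 / n
        assert above >= 95

    def test_soft_sweep_establishes_multiple_origins(self):
        cfg = SimConfig(sweep_kind="soft", selection_coefficient=0.2, n_origins=3,
                        target_frequency=0.5, seed=11, **SMALL)
        hap, truth = simulate_population(cfg)
        assert truth.n_origins == 3
        assert hap.derived_frequency(truth.sweep_site) >= 0.5

    def test_unestablishable_sweep_raises(self):
        cfg = SimConfig(sweep_kind="hard", selection_coefficient=0.0,
                        target_frequency=0.95, seed=3, max_restarts=2,
                        n_generations=150, n_haplotypes=100, n_sites=40,
                        sequence_length=10_000, focal_position=5_000,
                        burnin_generations=20)
        with pytest.raises(SweepNotEstablishedError):
            simulate_population(cfg)

    def test_neutral_sfs_is_monotone_decreasing(self):
        """Rank correlation of the mean site-frequency spectrum with 1/i."""
        n = 30
        spectrum = np.zeros(n - 1)
        for seed in range(100):
            cfg = SimConfig(n_haplotypes=n, n_sites=40, sequence_length=5_000,
                            focal_position=2_500, burnin_generations=30, seed=seed)
            hap, _ = simulate_population(cfg)
            counts = hap.alleles.sum(axis=0)
            for c in counts[(counts > 0) & (counts < n)]:
                spectrum[c - 1] += 1
        rho, _ = stats.spearmanr(spectrum, 1.0 / np.arange(1, n))
        assert rho > 0

    def test_two_population_split(self):
        cfg = SimConfig(n_populations=2, seed=5, **SMALL)
        hap, truth = simulate_population(cfg)
        assert set(truth.populations) == {0, 1}
        assert set(truth.true_te_frequencies["focal_te"]) == {"pop0", "pop1"}


def test_neutral_focal_marker_indistinguishable_from_neutral_snps():
    """Under s = 0 each sweep statistic at the focal marker has the same
    distribution as at frequency-matched neutral SNPs (two-sample KS)."""
    focal_vals = {"ihs": [], "nsl": [], "h12": []}
    neutral_vals = {"ihs": [], "nsl": [], "h12": []}
    for seed in range(80):
        cfg = SimConfig(sweep_kind="none", init_focal_frequency=0.5, seed=900 + seed,
                        n_haplotypes=100, n_sites=120, sequence_length=20_000,
                        focal_position=10_000, burnin_generations=80)
        hap, truth = simulate_population(cfg)
        site = truth.sweep_site
        f = hap.derived_frequency(site)
        if not 0.1 < f < 0.9:
            continue
        rng = np.random.default_rng(seed)
        matched = [
            s for s in np.flatnonzero(hap.neutral)
            if abs(hap.derived_frequency(int(s)) - f) < 0.1 and abs(int(s) - site) > 10
        ]
        picks = rng.choice(matched, size=min(2, len(matched)), replace=False)
        for name, fn in (("ihs", lambda h, s: ihs(h, s).unstd),
                         ("nsl", lambda h, s: nsl(h, s).unstd),
                         ("h12", lambda h, s: h12_window(h, s, window=40).h12)):
            try:
                focal_vals[name].append(fn(hap, site))
                for s in picks:
                    neutral_vals[name].append(fn(hap, int(s)))
            except ValueError:
                continue
    for name in ("ihs", "nsl", "h12"):
        a = np.array(focal_vals[name])
        b = np.array(neutral_vals[name])
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        assert len(a) > 20 and len(b) > 20
        _, p = stats.ks_2samp(a, b)
        assert p > 0.01, f"{name}: focal marker distribution deviates (p={p})"


class TestEmitters:
    samples = ["s1", "s2"]

    def _freqs(self, value):
        return pd.DataFrame({s: [value] for s in self.samples}, index=["TE1"])

    def test_fixed_te_has_no_absence_reads(self, rng):
        obs = emit_te_observations(self._freqs(1.0), "pooled", coverage=80, rng=rng)
        assert (obs["absence_reads"] == 0).all()

    def test_individual_mode_emits_one_call_per_strain(self, rng):
        obs = emit_te_observations(self._freqs(0.5), "individual", n_strains=20,
                                   no_data_rate=0.0, rng=rng)
        assert len(obs) == 20 * len(self.samples)
        assert set(obs["call"]) <= {"present", "absent", "polymorphic"}

    def test_pooled_estimates_unbiased_at_half(self, rng):
        freqs = pd.DataFrame({"s": [0.5] * 500}, index=[f"TE{i}" for i in range(500)])
        obs = emit_te_observations(freqs, "pooled", coverage=60, rng=rng)
        est = obs["presence_reads"] / (obs["presence_reads"] + obs["absence_reads"])
        se = math.sqrt(0.25 / 60 / 500)
        assert abs(est.mean() - 0.5) < 3 * se

    def test_nonpositive_coverage_rejected(self, rng):
        with pytest.raises(ValueError):
            emit_te_observations(self._freqs(0.5), "pooled", coverage=0, rng=rng)

    def test_emitters_deterministic_under_seed(self):
        a = emit_te_observations(self._freqs(0.4), "pooled", seed=9)
        b = emit_te_observations(self._freqs(0.4), "pooled", seed=9)
        pd.testing.assert_frame_equal(a, b)


def test_te_panel_archetypes(rng):
    tes, table = simulate_te_panel(60, ["a", "b", "c", "d"], rng)
    assert len(tes) == 60
    fixed = table[table["archetype"] == "fixed"]
    assert (fixed[["a", "b", "c", "d"]] > 0.95).all().all()
    low = table[table["archetype"] == "low"]
    assert (low[["a", "b", "c", "d"]] <= 0.10).all().all()


def test_vcf_round_trip(tmp_path):
    cfg = SimConfig(seed=2, **SMALL)
    hap, _ = simulate_population(cfg)
    path = tmp_path / "panel.vcf"
    write_vcf(hap, path)
    back = HaplotypeMatrix.from_vcf(path)
    assert np.array_equal(back.alleles, hap.alleles)
    assert np.array_equal(back.positions, hap.positions)
    assert np.array_equal(back.neutral, hap.neutral)
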