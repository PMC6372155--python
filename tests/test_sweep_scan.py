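"""Haplotype sweep statistics against hand enumeration and brute-force oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from teadapt.sweep_scan import (HaplotypeMatrix, NullDistribution, ehh_curve,
                                embed_te_marker, flag_h12, flag_ihs_nsl,
                                h12_window, ihs, nsl)


def hm(alleles, positions=None, **kw):
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(alleles.shape[1]) * 100
    return HaplotypeMatrix(alleles=alleles, positions=np.asarray(positions), **kw)


# ---------------------------------------------------------------------------
# brute-force oracles (independent pair-by-pair enumeration)
# ---------------------------------------------------------------------------

def ehh_oracle(alleles, core, allele, x):
    """EHH at site x: identical-pair fraction among core-allele carriers."""
    carriers = [h for h in range(alleles.shape[0]) if alleles[h, core] == allele]
    lo, hi = min(core, x), max(core, x)
    same = sum(
        1 for i, j in itertools.combinations(carriers, 2)
        if np.array_equal(alleles[i, lo:hi + 1], alleles[j, lo:hi + 1])
    )
    return same / math.comb(len(carriers), 2)


def ihs_oracle(hap, core, floor=0.05):
    """Trapezoidal iHH ratio built from the pairwise EHH oracle."""
    areas = {}
    for allele in (0, 1):
        area = 0.0
        for direction in (-1, +1):
            prev_e, prev_pos = 1.0, hap.positions[core]
            x = core + direction
            while 0 <= x < hap.n_sites:
                e = ehh_oracle(hap.alleles, core, allele, x)
                area += 0.5 * (prev_e + e) * abs(hap.positions[x] - prev_pos)
                prev_e, prev_pos = e, hap.positions[x]
                if e <= floor:
                    break
                x += direction
        areas[allele] = area
    return math.log(areas[0] / areas[1])


def nsl_oracle(alleles, core):
    """Mean pairwise identity-run length through the core, per allele class."""
    sl = {}
    for allele in (0, 1):
        carriers = [h for h in range(alleles.shape[0]) if alleles[h, core] == allele]
        lengths = []
        for i, j in itertools.combinations(carriers, 2):
            run = 1  # the core site
            x = core - 1
            while x >= 0 and alleles[i, x] == alleles[j, x]:
                run += 1
                x -= 1
            x = core + 1
            while x < alleles.shape[1] and alleles[i, x] == alleles[j, x]:
                run += 1
                x += 1
            lengths.append(run)
        sl[allele] = sum(lengths) / len(lengths)
    return math.log(sl[0] / sl[1])


def h12_oracle(alleles, lo, hi):
    counts = sorted(Counter(tuple(row) for row in alleles[:, lo:hi]).values(), reverse=True)
    p = np.array(counts) / sum(counts)
    h1 = float(np.sum(p**2))
    h12 = h1 + (2 * p[0] * p[1] if len(p) > 1 else 0.0)
    return h1, h1 - p[0] ** 2, h12


def neutral_matrix(rng, n_hap=40, n_sites=80):
    """Random haplotypes with site frequencies from a neutral-ish spectrum."""
    k = np.arange(1, n_hap)
    p = (1 / k) / np.sum(1 / k)
    counts = rng.choice(k, size=n_sites, p=p)
    alleles = np.zeros((n_hap, n_sites), dtype=np.int8)
    for j, c in enumerate(counts):
        alleles[rng.choice(n_hap, size=c, replace=False), j] = 1
    return hm(alleles, positions=np.sort(rng.choice(n_sites * 200, n_sites, replace=False)))


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        alleles = np.zeros((6, 7), dtype=int)
        alleles[:4, 3] = 1  # 4 identical derived haplotypes
        sites, values = ehh_curve(hm(alleles), 3, 1, +1)
        assert values[0] == 1.0 and np.all(values == 1.0)

    def test_two_two_split(self):
        alleles = np.zeros((4, 3), dtype=int)
        alleles[:, 1] = 1
        alleles[:2, 2] = 1  # carriers split 2 + 2 one site to the right
        _, values = ehh_curve(hm(alleles), 1, 1, +1)
        assert values[-1] == pytest.approx(2 / 6)

    def test_all_distinct_reaches_zero(self):
        alleles = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=int)
        _, values = ehh_curve(hm(alleles), 0, 1, +1)
        assert values[-1] == 0.0

    def test_monotone_non_increasing(self, rng):
        for _ in range(20):
            hap = neutral_matrix(rng)
            core = int(rng.integers(10, hap.n_sites - 10))
            if hap.derived_frequency(core) in (0.0, 1.0):
                continue
            for direction in (-1, +1):
                for allele in (0, 1):
                    if (hap.alleles[:, core] == allele).sum() < 2:
                        continue
                    _, values = ehh_curve(hap, core, allele, direction)
                    assert np.all(np.diff(values) <= 1e-12)

    def test_matches_pairwise_enumeration(self, rng):
        hap = neutral_matrix(rng, n_hap=20, n_sites=30)
        core = 15
        if hap.derived_frequency(core) in (0, 1):
            hap.alleles[:10, core] = 1
        sites, values = ehh_curve(hap, core, 1, +1)
        for x, v in zip(sites[1:6], values[1:6]):
            assert v == pytest.approx(ehh_oracle(hap.alleles, core, 1, int(x)))

    def test_fewer_than_two_carriers_rejected(self):
        alleles = np.zeros((4, 3), dtype=int)
        alleles[0, 1] = 1
        with pytest.raises(ValueError):
            ehh_curve(hm(alleles), 1, 1, +1)


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

class TestIhs:
    def test_symmetric_structure_gives_zero(self):
        # ancestral and derived carrier sets with mirrored haplotype structure
        block = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=int)
        alleles = np.hstack([block, np.array([[0], [0], [1], [1]]), block])
        res = ihs(hm(alleles), 2)
        assert res.unstd == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_negates(self, rng):
        hap = neutral_matrix(rng, n_hap=24, n_sites=40)
        core = 20
        freq = hap.derived_frequency(core)
        if freq in (0, 1) or min((hap.alleles[:, core] == 0).sum(),
                                 (hap.alleles[:, core] == 1).sum()) < 2:
            hap.alleles[:12, core] = 1
            hap.alleles[12:, core] = 0
        res = ihs(hap, core)
        swapped = hap.alleles.copy()
        swapped[:, core] = 1 - swapped[:, core]
        res_swapped = ihs(hm(swapped, positions=hap.positions), core)
        assert res_swapped.unstd == pytest.approx(-res.unstd, abs=1e-10)

    def test_worked_toy_against_hand_trapezoids(self):
        """8 haplotypes, 3 sites each side: derived carriers identical across
        the window, ancestral carriers all distinct after one site."""
        derived = np.tile([0, 0, 0, 1, 0, 0, 0], (4, 1))
        ancestral = np.array([
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 1, 0, 1, 0, 0],
            [0, 1, 0, 0, 0, 1, 0],
            [0, 1, 1, 0, 1, 1, 0],
        ])
        alleles = np.vstack([derived, ancestral])
        positions = np.arange(7) * 100
        res = ihs(hm(alleles, positions), 3, ehh_floor=0.0)
        # derived: EHH stays 1 for three steps each side -> area 2 * 300
        # ancestral: EHH drops to 2/6 after one step, 0 after two
        #   area per side = (1 + 1/3)/2 * 100 + (1/3 + 0)/2 * 100 = 66.67 + 16.67
        ihh_d = 600.0
        ihh_a = 2 * ((1 + 1 / 3) / 2 * 100 + (1 / 3) / 2 * 100)
        assert res.ihh_derived == pytest.approx(ihh_d)
        assert res.ihh_ancestral == pytest.approx(ihh_a)
        assert res.unstd == pytest.approx(math.log(ihh_a / ihh_d))

    def test_matches_brute_force_oracle(self, rng):
        """Full agreement with the pairwise-enumeration iHS on random data."""
        checked = 0
        while checked < 25:
            hap = neutral_matrix(rng, n_hap=24, n_sites=50)
            core = int(rng.integers(20, 30))
            col = hap.alleles[:, core]
            if min((col == 0).sum(), (col == 1).sum()) < 2:
                continue
            res = ihs(hap, core)
            if not res.defined:
                continue
            assert res.unstd == pytest.approx(ihs_oracle(hap, core), abs=1e-10)
            checked += 1


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

class TestNsl:
    def test_symmetric_structure_gives_zero(self):
        block = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=int)
        alleles = np.hstack([block, np.array([[0], [0], [1], [1]]), block])
        assert nsl(hm(alleles), 2).unstd == pytest.approx(0.0, abs=1e-12)

    def test_shared_run_lengths(self):
        """4 derived carriers identical over 10 flanking sites vs 4 ancestral
        carriers identical over 5: exact pairwise shared-run enumeration."""
        n_flank = 10
        derived = np.zeros((4, 2 * n_flank + 1), dtype=int)
        derived[:, n_flank] = 1
        ancestral = np.zeros((4, 2 * n_flank + 1), dtype=int)
        # break ancestral identity 5 sites away on each side, per haplotype
        for k in range(4):
            if k:
                ancestral[k, n_flank - 5] = 1
                ancestral[k, n_flank + 5] = 1
        # make the breaks distinct so every ancestral pair diverges there
        ancestral[1, n_flank - 6] = 1
        ancestral[2, n_flank + 6] = 1
        alleles = np.vstack([derived, ancestral])
        res = nsl(hm(alleles), n_flank)
        assert res.unstd == pytest.approx(nsl_oracle(alleles, n_flank), abs=1e-12)
        assert res.ihh_derived == pytest.approx(2 * n_flank + 1)  # full identity

    def test_label_swap_negates(self, rng):
        hap = neutral_matrix(rng, n_hap=20, n_sites=40)
        core = 20
        col = hap.alleles[:, core]
        if min((col == 0).sum(), (col == 1).sum()) < 2:
            hap.alleles[:10, core] = 1
            hap.alleles[10:, core] = 0
        res = nsl(hap, core)
        swapped = hap.alleles.copy()
        swapped[:, core] = 1 - swapped[:, core]
        res_swapped = nsl(hm(swapped, positions=hap.positions), core)
        assert res_swapped.unstd == pytest.approx(-res.unstd, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        checked = 0
        while checked < 25:
            hap = neutral_matrix(rng, n_hap=16, n_sites=40)
            core = int(rng.integers(15, 25))
            col = hap.alleles[:, core]
            if min((col == 0).sum(), (col == 1).sum()) < 2:
                continue
            res = nsl(hap, core)
            if not res.defined:
                continue
            assert res.unstd == pytest.approx(nsl_oracle(hap.alleles, core), abs=1e-10)
            checked += 1

    def test_missing_data_rejected(self):
        alleles = np.zeros((4, 5), dtype=int)
        alleles[:2, 2] = 1
        alleles[0, 0] = -1
        with pytest.raises(ValueError, match="missing"):
            nsl(hm(alleles), 2)

    def test_binwise_standardization_is_exact(self, rng):
        """Standardized null values have mean 0 and sd 1 inside every bin."""
        values = rng.normal(size=2000)
        freqs = rng.uniform(0.02, 0.98, size=2000)
        null = NullDistribution("nsl", values, freqs, n_bins=10, binning="count")
        table = null.bin_table()
        for _, row in table.iterrows():
            sel = (null.freqs > row["bin_lo"]) & (null.freqs <= row["bin_hi"])
            if sel.sum() > 1:
                z = null.std_values[sel]
                assert abs(z.mean()) < 1e-9
                assert z.std() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# H12
# ---------------------------------------------------------------------------

class TestH12:
    def test_spectrum_3_2_1(self):
        rows = [[0, 0, 0, 0]] * 3 + [[1, 1, 0, 0]] * 2 + [[1, 0, 1, 0]]
        res = h12_window(hm(np.array(rows)), 1, window=4)
        assert res.h1 == pytest.approx(14 / 36)
        assert res.h12 == pytest.approx(26 / 36)
        assert res.h2 == pytest.approx(5 / 36)

    def test_all_identical(self):
        res = h12_window(hm(np.zeros((6, 4), dtype=int)), 1, window=4)
        assert res.h1 == res.h12 == 1.0 and res.h2 == 0.0

    def test_top_haplotype_te_fraction(self):
        rows = [[0, 0, 0, 0]] * 3 + [[1, 1, 0, 0]] * 2 + [[1, 0, 1, 0]]
        te_states = [1, 1, 1, 0, 0, 0]  # the majority haplotype carries the TE
        res = h12_window(hm(np.array(rows)), 1, window=4, te_states=te_states)
        assert res.te_fractions[0] == 1.0

    def test_invariants_on_random_windows(self, rng):
        for _ in range(50):
            hap = neutral_matrix(rng, n_hap=20, n_sites=30)
            res = h12_window(hap, 15, window=10)
            assert 0.0 <= res.h2 <= res.h1 <= res.h12 <= 1.0
            assert res.spectrum.sum() == pytest.approx(1.0)

    def test_matches_counter_oracle(self, rng):
        hap = neutral_matrix(rng, n_hap=30, n_sites=40)
        res = h12_window(hap, 20, window=11)
        h1, h2, h12 = h12_oracle(hap.alleles, *res.window)
        assert (res.h1, res.h2, res.h12) == (pytest.approx(h1), pytest.approx(h2), pytest.approx(h12))

    def test_edge_window_shrinks_and_flags(self, rng):
        hap = neutral_matrix(rng, n_hap=10, n_sites=30)
        res = h12_window(hap, 2, window=20)
        assert res.shrunk and res.window[0] == 0


# ---------------------------------------------------------------------------
# embedding and significance calibration
# ---------------------------------------------------------------------------

class TestEmbedding:
    def test_marker_inserted_in_position_order(self, rng):
        hap = neutral_matrix(rng, n_hap=10, n_sites=20)
        states = rng.integers(0, 2, size=10)
        pos = int(hap.positions[5]) + 1
        out, site = embed_te_marker(hap, states, pos)
        assert out.n_sites == hap.n_sites + 1
        assert np.all(np.diff(out.positions) > 0)
        assert np.array_equal(out.alleles[:, site], states)

    def test_tie_placed_after_existing_snp(self, rng):
        hap = neutral_matrix(rng, n_hap=10, n_sites=20)
        states = np.ones(10, dtype=int)
        pos = int(hap.positions[5])
        out, site = embed_te_marker(hap, states, pos)
        assert site == 6  # immediately after the coinciding SNP
        assert np.all(np.diff(out.positions) > 0)


class TestCalibration:
    def test_null_median_never_flagged(self, rng):
        null = NullDistribution("ihs", rng.normal(size=1000), rng.uniform(0.1, 0.9, 1000))
        med = float(np.median(null.std_values))
        assert flag_ihs_nsl({"te": med}, null)["te"] is False

    def test_two_sided_self_test_rate(self, rng):
        values = rng.normal(size=2000)
        freqs = rng.uniform(0.05, 0.95, size=2000)
        null = NullDistribution("ihs", values, freqs, n_bins=20)
        flags = flag_ihs_nsl(
            {f"s{i}": z for i, z in enumerate(null.std_values)}, null, alpha=0.05)
        rate = np.mean(list(flags.values()))
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * se

    def test_h12_membership_rule(self, rng):
        null = NullDistribution("h12", rng.uniform(0, 0.5, size=1000))
        strong = h12_window(hm(np.zeros((6, 5), dtype=int)), 2, window=5,
                            te_states=[1, 1, 1, 1, 0, 0])
        weak = h12_window(hm(np.zeros((6, 5), dtype=int)), 2, window=5,
                          te_states=[1, 0, 0, 0, 0, 0])
        flags = flag_h12({"strong": strong, "weak": weak}, null)
        assert flags["strong"] is True
        assert flags["weak"] is False  # top haplotype carries the TE in < 50% of strains
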