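"""Haplotype-based selective-sweep statistics at TE markers.

A TE insertion is treated as a biallelic marker: presence is the derived
allele, absence the ancestral, and the marker is embedded at the TE midpoint
inside the phased SNP haplotypes of the population.  Three statistics are
computed from scratch:

* **EHH / iHS** — extended haplotype homozygosity decays away from the core
  site; the integrated EHH (iHH) of the derived vs ancestral allele,
  ``ln(iHH_A / iHH_D)``, is large in magnitude when one allele sits on an
  unusually long shared haplotype, the classic hard-sweep signal.
* **nSL** — the same contrast with haplotype length measured in number of
  segregating sites instead of map distance, which buys robustness to
  recombination-rate variation.
* **H1/H2/H12** — the haplotype-frequency spectrum of a fixed window of SNPs
  around the core; H12 pools the two most frequent haplotypes and therefore
  also picks up soft sweeps, where several haplotypes carry the adaptive
  allele.

Significance is empirical throughout: each statistic computed at TEs is
compared with its distribution at designated neutral SNPs (short-intron-like
sites), stratified by the marker's frequency in the ancestral (African)
population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
EHH_FLOOR = 0.05
H12_WINDOW = 100  # SNPs
IHS_BINS = 20  # equal-width derived-frequency bins
NSL_BINS = 10  # equal-count derived-frequency bins
H12_TOP_FRACTION = 0.15
H12_MEMBERSHIP_CUT = 0.5
NULL_MIN_VALUES = 100


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased haplotypes x sites, alleles in {0 ancestral, 1 derived, -1 missing}."""

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "2L"
    genetic_positions: np.ndarray | None = None
    neutral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[0] < 2:
            raise ValueError("need at least two haplotypes")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions do not match the allele matrix")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.neutral is None:
            self.neutral = np.zeros(self.n_sites, dtype=bool)
        else:
            self.neutral = np.asarray(self.neutral, dtype=bool)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_frequency(self, site: int) -> float:
        col = self.alleles[:, site]
        ok = col != MISSING
        if not ok.any():
            return float("nan")
        return float(col[ok].mean())

    def site_distance(self, i: int, j: int) -> float:
        """Map distance between two sites (genetic map if present, else bp)."""
        if self.genetic_positions is not None:
            return abs(float(self.genetic_positions[i] - self.genetic_positions[j]))
        return abs(float(self.positions[i] - self.positions[j]))

    def drop_missing(self) -> "HaplotypeMatrix":
        """Remove haplotypes, then sites, that still contain missing data."""
        keep_h = ~(self.alleles == MISSING).any(axis=1)
        if keep_h.sum() < 2:  # fall back to pruning sites first
            keep_h = np.ones(self.n_haplotypes, dtype=bool)
        alleles = self.alleles[keep_h]
        keep_s = ~(alleles == MISSING).any(axis=0)
        return HaplotypeMatrix(
            alleles=alleles[:, keep_s],
            positions=self.positions[keep_s],
            chrom=self.chrom,
            genetic_positions=None if self.genetic_positions is None else self.genetic_positions[keep_s],
            neutral=self.neutral[keep_s],
        )

    @classmethod
    def from_vcf(cls, path) -> "HaplotypeMatrix":
        """Read phased GT columns from a VCF 4.2 file (two haplotypes per sample).

        Sites flagged ``NEUT`` in INFO become the neutral-SNP set.
        """
        import cyvcf2

        vcf = cyvcf2.VCF(str(path))
        cols, positions, neutral = [], [], []
        chrom = None
        for var in vcf:
            chrom = var.CHROM
            gt = np.array(var.genotypes)[:, :2]  # n_sample x 2
            cols.append(gt.reshape(-1))
            positions.append(var.POS - 1)
            neutral.append(bool(var.INFO.get("NEUT")))
        if not cols:
            raise ValueError(f"no variants in {path}")
        alleles = np.stack(cols, axis=1).astype(np.int8)
        return cls(
            alleles=alleles, positions=np.array(positions), chrom=chrom,
            neutral=np.array(neutral),
        )


def embed_te_marker(
    hap: HaplotypeMatrix, te_states: Sequence[int], position: int
) -> tuple[HaplotypeMatrix, int]:
    """Insert a TE presence/absence marker at its midpoint coordinate.

    ``te_states`` gives one value per haplotype: presence = 1 (derived),
    absence = 0 (ancestral), polymorphic / no data = -1 (missing).  When the
    midpoint coincides with an existing SNP the marker goes immediately after
    it (stable order, positions nudged by the caller remain untouched).
    """
    states = np.asarray(te_states, dtype=np.int8)
    if states.size != hap.n_haplotypes:
        raise ValueError("one TE state per haplotype required")
    site = int(np.searchsorted(hap.positions, position, side="right"))
    alleles = np.insert(hap.alleles, site, states, axis=1)
    positions = np.insert(hap.positions, site, position).astype(float)
    # on a positional tie the marker sits immediately after the SNP; keep the
    # coordinate axis strictly increasing with a half-bp nudge
    if site > 0 and positions[site] <= positions[site - 1]:
        positions[site] = positions[site - 1] + 0.5
    neutral = np.insert(hap.neutral, site, False)
    gpos = None
    if hap.genetic_positions is not None:
        left = hap.genetic_positions[site - 1] if site > 0 else hap.genetic_positions[0]
        right = hap.genetic_positions[site] if site < hap.n_sites else hap.genetic_positions[-1]
        gpos = np.insert(hap.genetic_positions, site, (left + right) / 2.0)
    out = HaplotypeMatrix(
        alleles=alleles, positions=positions, chrom=hap.chrom,
        genetic_positions=gpos, neutral=neutral,
    )
    return out, site


# ---------------------------------------------------------------------------
# EHH and iHS
# ---------------------------------------------------------------------------

def ehh_curve(
    hap: HaplotypeMatrix, core_site: int, core_allele: int, direction: int,
    stop_below: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH of ``core_allele`` carriers from the core outwards.

    ``direction`` is +1 (increasing positions) or -1.  Returns (site indices,
    EHH values); the first entry is the core itself with EHH = 1.  EHH(x) is
    the probability that two random carrier haplotypes are identical over all
    sites from the core to x; the denominator stays fixed at the number of
    carrier pairs at the core, so haplotypes dropped for missing data only
    ever reduce EHH and the curve is non-increasing.  Walking stops once EHH
    falls to ``stop_below`` or below (the triggering site is included).
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    col = hap.alleles[:, core_site]
    carriers = np.flatnonzero(col == core_allele)
    n0 = carriers.size
    if n0 < 2:
        raise ValueError("fewer than two carriers of the core allele")
    denom = n0 * (n0 - 1) / 2.0
    group = np.zeros(n0, dtype=np.int64)
    sites = [core_site]
    values = [1.0]
    site = core_site + direction
    while 0 <= site < hap.n_sites:
        col = hap.alleles[carriers, site]
        keep = col != MISSING
        carriers, group, col = carriers[keep], group[keep], col[keep]
        if carriers.size < 2:
            sites.append(site)
            values.append(0.0)
            break
        _, group = np.unique(group * 2 + col, return_inverse=True)
        counts = np.bincount(group)
        hh = float(np.sum(counts * (counts - 1) / 2.0) / denom)
        sites.append(site)
        values.append(hh)
        if hh <= stop_below:
            break
        site += direction
    return np.array(sites), np.array(values)


@dataclass
class IhsResult:
    site: int
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    unstd: float
    std: float = float("nan")
    truncated: bool = False
    defined: bool = True


def _integrate_ehh(
    hap: HaplotypeMatrix, core_site: int, allele: int, floor: float, max_gap: float | None,
) -> tuple[float, bool]:
    """Trapezoidal iHH for one allele, summing both directions from the core."""
    area = 0.0
    truncated = False
    for direction in (-1, +1):
        sites, values = ehh_curve(hap, core_site, allele, direction, stop_below=floor)
        stopped = values[-1] <= floor
        for k in range(1, len(sites)):
            step = hap.site_distance(sites[k - 1], sites[k])
            if max_gap is not None and step > max_gap:
                truncated = True
                break
            area += 0.5 * (values[k - 1] + values[k]) * step
        if not stopped:
            truncated = True  # hit the chromosome end with EHH still above floor
    return area, truncated


def ihs(
    hap: HaplotypeMatrix, core_site: int,
    ehh_floor: float = EHH_FLOOR, max_gap: float | None = None,
    standardization: "NullDistribution | None" = None,
) -> IhsResult:
    """Unstandardized (and optionally standardized) iHS at a core site.

    ``unstd = ln(iHH_ancestral / iHH_derived)``; positive values mean the
    ancestral allele rides the longer haplotypes, strongly negative values
    are the classic signature of a recent sweep on the derived allele.
    """
    # haplotypes with a missing state at the core belong to neither allele
    # class and are simply excluded from both EHH computations
    freq = hap.derived_frequency(core_site)
    if math.isnan(freq) or not 0 < freq < 1:
        raise ValueError("core site must be biallelic in the sample")
    try:
        ihh_a, trunc_a = _integrate_ehh(hap, core_site, 0, ehh_floor, max_gap)
        ihh_d, trunc_d = _integrate_ehh(hap, core_site, 1, ehh_floor, max_gap)
    except ValueError:
        return IhsResult(core_site, freq, float("nan"), float("nan"), float("nan"), defined=False)
    if ihh_a <= 0 or ihh_d <= 0:
        return IhsResult(core_site, freq, ihh_a, ihh_d, float("nan"), defined=False)
    unstd = math.log(ihh_a / ihh_d)
    res = IhsResult(core_site, freq, ihh_a, ihh_d, unstd, truncated=trunc_a or trunc_d)
    if standardization is not None:
        res.std = float(standardization.standardize([unstd], [freq])[0])
    return res


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

def _pairwise_run_lengths(block: np.ndarray, core: int) -> np.ndarray:
    """For every haplotype pair: # consecutive identical sites through the core.

    ``block`` is carriers x sites with no missing data; runs extend left and
    right from the core until the first mismatch on that side, and the core
    site itself counts once.
    """
    nc = block.shape[0]
    ii, jj = np.triu_indices(nc, k=1)
    total = np.ones(ii.size)  # the core site, where all carriers agree
    for direction in (-1, +1):
        alive = np.ones(ii.size, dtype=bool)
        site = core + direction
        while 0 <= site < block.shape[1] and alive.any():
            alive &= block[ii, site] == block[jj, site]
            total += alive
            site += direction
    return total


def nsl(
    hap: HaplotypeMatrix, core_site: int, standardization: "NullDistribution | None" = None
) -> IhsResult:
    """Unstandardized nSL at a core site (haplotype length in segregating sites).

    For each allele class, SL is the mean over carrier pairs of the number of
    consecutive sites (through the core) over which the pair is identical;
    ``unstd = ln(SL_ancestral / SL_derived)``.  The matrix must be free of
    missing data — remove affected strains and positions first
    (:meth:`HaplotypeMatrix.drop_missing`).
    """
    if np.any(hap.alleles == MISSING):
        raise ValueError("nSL requires a matrix with no missing data; use drop_missing()")
    freq = hap.derived_frequency(core_site)
    if not 0 < freq < 1:
        raise ValueError("core site must be biallelic in the sample")
    col = hap.alleles[:, core_site]
    sl = {}
    for allele in (0, 1):
        rows = np.flatnonzero(col == allele)
        if rows.size < 2:
            return IhsResult(core_site, freq, float("nan"), float("nan"), float("nan"), defined=False)
        sl[allele] = float(_pairwise_run_lengths(hap.alleles[rows], core_site).mean())
    if sl[0] <= 0 or sl[1] <= 0:
        return IhsResult(core_site, freq, sl[0], sl[1], float("nan"), defined=False)
    unstd = math.log(sl[0] / sl[1])
    res = IhsResult(core_site, freq, sl[0], sl[1], unstd)
    if standardization is not None:
        res.std = float(standardization.standardize([unstd], [freq])[0])
    return res


# ---------------------------------------------------------------------------
# H12 and the haplotype spectrum
# ---------------------------------------------------------------------------

@dataclass
class H12Result:
    site: int
    h1: float
    h2: float
    h12: float
    spectrum: np.ndarray
    te_fractions: list[float] = field(default_factory=list)
    window: tuple[int, int] = (0, 0)
    shrunk: bool = False

    def max_top_te_fraction(self) -> float:
        return max(self.te_fractions, default=float("nan"))


def h12_window(
    hap: HaplotypeMatrix, core_site: int, window: int = H12_WINDOW,
    te_states: Sequence[int] | None = None,
) -> H12Result:
    """Haplotype-homozygosity spectrum statistics in a SNP window at the core.

    The window covers ``window`` sites centered on the core (shrunk, and
    flagged, at chromosome ends).  Haplotypes with missing data anywhere in
    the window are dropped.  With ``te_states`` given, the fraction of TE
    carriers among the members of each of the three most frequent haplotype
    groups is reported, which feeds the H12 significance rule.
    """
    left_want = (window - 1) // 2
    right_want = window - 1 - left_want
    lo = max(0, core_site - left_want)
    hi = min(hap.n_sites, core_site + right_want + 1)
    shrunk = (core_site - lo) < left_want or (hi - core_site - 1) < right_want
    block = hap.alleles[:, lo:hi]
    keep = ~(block == MISSING).any(axis=1)
    block = block[keep]
    if block.shape[0] < 2:
        raise ValueError("fewer than two complete haplotypes in the window")
    _, inverse, counts = np.unique(block, axis=0, return_inverse=True, return_counts=True)
    order = np.argsort(counts)[::-1]
    p = counts[order] / counts.sum()
    h1 = float(np.sum(p**2))
    h2 = h1 - float(p[0] ** 2)
    h12 = h1 + (2.0 * p[0] * p[1] if p.size > 1 else 0.0)
    te_fracs: list[float] = []
    if te_states is not None:
        states = np.asarray(te_states)[keep]
        for rank in range(min(3, p.size)):
            members = inverse == order[rank]
            known = states[members] != MISSING
            if known.sum() == 0:
                te_fracs.append(float("nan"))
            else:
                te_fracs.append(float((states[members][known] == 1).mean()))
    return H12Result(
        site=core_site, h1=h1, h2=h2, h12=h12, spectrum=p,
        te_fractions=te_fracs, window=(lo, hi), shrunk=shrunk,
    )


# ---------------------------------------------------------------------------
# empirical nulls and significance
# ---------------------------------------------------------------------------

class NullDistribution:
    """Empirical distribution of a statistic at designated neutral SNPs.

    Also carries the frequency-bin standardization table: the values are
    binned by derived-allele frequency (``binning="width"`` for equal-width
    bins, Voight-style, or ``"count"`` for equal-occupancy bins) and each
    value is reduced to a z-score against its bin mean and SD.
    """

    def __init__(
        self, name: str, values, freqs=None, stratum: str = "all",
        n_bins: int = IHS_BINS, binning: str = "width",
    ):
        values = np.asarray(values, dtype=float)
        ok = ~np.isnan(values)
        self.name = name
        self.stratum = stratum
        self.values = values[ok]
        if self.values.size < NULL_MIN_VALUES:
            logger.warning(
                "null distribution %s/%s built from only %d neutral values",
                name, stratum, self.values.size,
            )
        self._edges = None
        self._bin_mean = None
        self._bin_sd = None
        if freqs is not None:
            freqs = np.asarray(freqs, dtype=float)[ok]
            self.freqs = freqs
            if binning == "width":
                edges = np.linspace(0.0, 1.0, n_bins + 1)
            elif binning == "count":
                qs = np.linspace(0.0, 1.0, n_bins + 1)
                edges = np.unique(np.quantile(freqs, qs))
                edges[0], edges[-1] = 0.0, 1.0
            else:
                raise ValueError("binning must be 'width' or 'count'")
            idx = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, len(edges) - 2)
            overall_sd = float(self.values.std()) or 1.0
            mean = np.zeros(len(edges) - 1)
            sd = np.full(len(edges) - 1, overall_sd)
            for b in range(len(edges) - 1):
                sel = idx == b
                if sel.sum() >= 2:
                    mean[b] = self.values[sel].mean()
                    bin_sd = self.values[sel].std()
                    if bin_sd > 0:
                        sd[b] = bin_sd
                elif sel.sum() == 1:
                    mean[b] = self.values[sel].mean()
            self._edges, self._bin_mean, self._bin_sd = edges, mean, sd
            self.std_values = self.standardize(self.values, freqs)
        else:
            self.freqs = None
            self.std_values = self.values.copy()

    def standardize(self, values, freqs) -> np.ndarray:
        if self._edges is None:
            return np.asarray(values, dtype=float)
        values = np.asarray(values, dtype=float)
        freqs = np.asarray(freqs, dtype=float)
        idx = np.clip(np.searchsorted(self._edges, freqs, side="right") - 1, 0, len(self._edges) - 2)
        return (values - self._bin_mean[idx]) / self._bin_sd[idx]

    def abs_threshold(self, alpha: float = 0.05) -> float:
        """|z| exceeded by an ``alpha`` fraction of the (standardized) null."""
        return float(np.percentile(np.abs(self.std_values), 100 * (1 - alpha)))

    def upper_threshold(self, top_fraction: float) -> float:
        return float(np.percentile(self.values, 100 * (1 - top_fraction)))

    def bin_table(self) -> pd.DataFrame:
        if self._edges is None:
            raise ValueError("no frequency bins were built")
        return pd.DataFrame({
            "bin_lo": self._edges[:-1], "bin_hi": self._edges[1:],
            "mean": self._bin_mean, "sd": self._bin_sd,
        })


def flag_ihs_nsl(
    std_values: Mapping[str, float], null: NullDistribution,
    alpha: float = 0.05, two_sided: bool = True,
) -> dict[str, bool]:
    """Empirical iHS/nSL significance: outside the null's 5% tail mass.

    Two-sided by default (|z| beyond the 95th percentile of the null's |z|);
    the one-sided variant flags only values below the alpha quantile, i.e.
    sweeps on the derived allele.
    """
    if null.std_values.size == 0:
        raise ValueError("empty null distribution")
    if two_sided:
        cut = null.abs_threshold(alpha)
        return {k: bool(abs(v) > cut) for k, v in std_values.items() if not math.isnan(v)}
    cut = float(np.percentile(null.std_values, 100 * alpha))
    return {k: bool(v < cut) for k, v in std_values.items() if not math.isnan(v)}


def flag_h12(
    results: Mapping[str, H12Result], null: NullDistribution,
    top_fraction: float = H12_TOP_FRACTION, membership_cut: float = H12_MEMBERSHIP_CUT,
) -> dict[str, bool]:
    """H12 significance: top of the neutral distribution plus TE membership.

    A TE passes when its H12 lies in the top ``top_fraction`` of the null
    AND at least one of its three most frequent window haplotypes is carried
    by >= ``membership_cut`` of the member strains.
    """
    if null.values.size == 0:
        raise ValueError("empty null distribution")
    cut = null.upper_threshold(top_fraction)
    out = {}
    for te_id, res in results.items():
        frac = res.max_top_te_fraction()
        out[te_id] = bool(res.h12 > cut and not math.isnan(frac) and frac >= membership_cut)
    return out


def neutral_statistics(
    hap: HaplotypeMatrix, tests: Iterable[str] = ("ihs", "nsl", "h12"),
    max_sites: int | None = None, rng: np.random.Generator | None = None,
    h12_snp_window: int = H12_WINDOW, ehh_floor: float = EHH_FLOOR,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Compute sweep statistics at the neutral-flagged SNPs of a matrix.

    The result (one row per usable neutral site, with the site's derived
    frequency) is the raw material for :class:`NullDistribution`.  With
    ``max_sites`` set, a random subset of neutral sites is used.
    """
    sites = np.flatnonzero(hap.neutral)
    freqs = np.array([hap.derived_frequency(s) for s in sites])
    sites = sites[(freqs >= min_maf) & (freqs <= 1 - min_maf)]
    if max_sites is not None and sites.size > max_sites:
        rng = rng or np.random.default_rng()
        sites = np.sort(rng.choice(sites, size=max_sites, replace=False))
    has_missing = bool(np.any(hap.alleles == MISSING))
    nomiss = hap.drop_missing() if has_missing else hap
    rows = []
    for s in sites:
        row: dict[str, float] = {"site": int(s), "freq": hap.derived_frequency(int(s))}
        if "ihs" in tests:
            try:
                row["ihs_unstd"] = ihs(hap, int(s), ehh_floor=ehh_floor).unstd
            except ValueError:
                row["ihs_unstd"] = float("nan")
        if "nsl" in tests:
            try:
                # site indices shift when missing rows/columns are pruned
                ns = int(np.searchsorted(nomiss.positions, hap.positions[s]))
                if ns >= nomiss.n_sites or nomiss.positions[ns] != hap.positions[s]:
                    raise ValueError("site pruned with missing data")
                row["nsl_unstd"] = nsl(nomiss, ns).unstd
            except ValueError:
                row["nsl_unstd"] = float("nan")
        if "h12" in tests:
            try:
                row["h12"] = h12_window(hap, int(s), window=h12_snp_window).h12
            except ValueError:
                row["h12"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
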