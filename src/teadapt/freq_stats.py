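"""Allele-frequency evidence of selection: Weir-Cockerham FST and Tajima's D.

Population differentiation at a TE locus is measured with the Weir &
Cockerham (1984) variance-components FST estimator for a pair of populations,
in its haploid form (no heterozygosity term), which is appropriate for phased
haplotypes and inbred strain panels.  Significance is empirical: the TE's
theta is compared with the 95th percentile of theta at putatively neutral
SNPs, stratified by the locus's frequency in the ancestral-range (African)
population, and calls across population pairs are filtered for latitudinal
concordance.

For fixed TEs — invisible to frequency contrasts — evidence comes from
Tajima's D in non-overlapping 500-bp windows: a significantly negative D in a
window at or near the insertion indicates an excess of rare variants, as left
behind by a recent sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOME_TAJIMA_CUT = -1.65
X_TAJIMA_CUT = -1.82
TAJIMA_WINDOW = 500  # bp
TAJIMA_PROXIMITY = 500  # bp; one window
AFRICAN_HIGH_CUT = 0.10
FST_PERCENTILE = 95.0


@dataclass
class FstResult:
    """WC84 variance components and theta for one locus and population pair."""

    locus_id: str
    pair: tuple[str, str]
    a: float  # among-population component
    b: float  # within-population component
    c: float  # within-individual component (0 for haploid data)
    theta: float
    direction: str  # population with the higher derived-allele frequency
    defined: bool = True
    significant: bool | None = None


def wc_fst(
    n1: int, derived1: int, n2: int, derived2: int,
    pair: tuple[str, str] = ("pop1", "pop2"), locus_id: str = "",
) -> FstResult:
    """Weir-Cockerham (1984) pairwise FST from haploid allele counts.

    ``n_i`` is the number of sampled alleles and ``derived_i`` the derived
    count in population i.  A locus monomorphic for the same allele in both
    populations has no variance to partition and is returned flagged
    undefined.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 sampled alleles per population")
    if not (0 <= derived1 <= n1 and 0 <= derived2 <= n2):
        raise ValueError("derived counts out of range")
    p1, p2 = derived1 / n1, derived2 / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    if pbar in (0.0, 1.0):
        return FstResult(locus_id, pair, 0.0, 0.0, 0.0, float("nan"), "tie", defined=False)
    # diploid WC84 components with average heterozygosity 0 (haploid data)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    c = 0.0
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    if p1 > p2:
        direction = pair[0]
    elif p2 > p1:
        direction = pair[1]
    else:
        direction = "tie"
    return FstResult(locus_id, pair, a, b, c, theta, direction, defined=denom != 0)


def pooled_pseudocounts(freq: float, n_strains: int, total_reads: int) -> tuple[int, int]:
    """Convert a pooled frequency estimate into pseudo allele counts.

    The effective number of sampled alleles is capped both by the pool size
    (2 x n_strains chromosomes) and by the read support behind the estimate.
    """
    if not 0 <= freq <= 1:
        raise ValueError("frequency outside [0, 1]")
    n_eff = max(2, min(2 * n_strains, total_reads))
    return n_eff, int(round(freq * n_eff))


def fst_significance(
    te_theta: Mapping[str, float],
    null_theta: Mapping[str, Sequence[float]],
    african_freq: Mapping[str, float],
    high_cut: float = AFRICAN_HIGH_CUT,
    percentile: float = FST_PERCENTILE,
) -> dict[str, bool]:
    """Empirical FST significance against frequency-stratified neutral nulls.

    ``null_theta`` maps stratum name (``"AF_high"`` / ``"AF_low"``) to neutral
    SNP theta values.  A TE is compared with the stratum matching its African
    frequency; TEs with no African frequency are skipped (a stratum is never
    assumed), and an empty required stratum is an error.
    """
    thresholds = {}
    for stratum in ("AF_high", "AF_low"):
        values = np.asarray(null_theta.get(stratum, []), dtype=float)
        values = values[~np.isnan(values)]
        thresholds[stratum] = (
            float(np.percentile(values, percentile)) if values.size else None
        )
        if values.size and values.size < 100:
            logger.warning("FST null stratum %s has only %d values", stratum, values.size)
    flags: dict[str, bool] = {}
    for te_id, theta in te_theta.items():
        af = african_freq.get(te_id)
        if af is None or (isinstance(af, float) and np.isnan(af)):
            logger.warning("TE %s has no African frequency; FST significance skipped", te_id)
            continue
        stratum = "AF_high" if af > high_cut else "AF_low"
        cut = thresholds[stratum]
        if cut is None:
            raise ValueError(f"empty FST null stratum {stratum}")
        flags[te_id] = bool(theta > cut)
    return flags


def concordance_filter(records: pd.DataFrame, min_pairs: int = 2) -> set[str]:
    """Latitude-concordant FST candidates.

    ``records`` has one row per TE x population pair with columns ``te_id``,
    ``pair``, ``significant`` and ``high_side`` (the latitude class —
    ``"high"`` or ``"low"`` — of the population where the TE is at higher
    frequency).  A TE is kept when it is significant in at least ``min_pairs``
    pairs and the high-frequency side is the same in every significant pair.
    """
    required = {"te_id", "pair", "significant", "high_side"}
    if not required.issubset(records.columns):
        raise ValueError(f"concordance records need columns {sorted(required)}")
    kept: set[str] = set()
    for te_id, sub in records.groupby("te_id"):
        sig = sub[sub["significant"].astype(bool)]
        if len(sig) < min_pairs:
            continue
        sides = set(sig["high_side"])
        if len(sides) == 1:
            kept.add(te_id)
    return kept


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d(alleles: np.ndarray) -> tuple[float, int, float]:
    """Tajima's D for an n x S 0/1 allele matrix.

    Returns ``(D, S, pi)`` where S is the number of segregating sites and pi
    the mean number of pairwise differences.  D is NaN when S = 0.
    """
    alleles = np.asarray(alleles)
    n = alleles.shape[0]
    if n < 4:
        raise ValueError("need >= 4 sequences")
    counts = alleles.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan"), 0, 0.0
    c = counts[seg].astype(float)
    pi = float(np.sum(c * (n - c)) / (n * (n - 1) / 2))
    k = _tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = (pi - theta_w) / np.sqrt(var)
    return float(D), S, pi


@dataclass
class TajimaWindow:
    chrom: str
    start: int
    end: int
    S: int
    pi: float
    D: float
    significant: bool = False


def tajima_windows(
    alleles: np.ndarray, positions: np.ndarray, chrom: str,
    chrom_length: int | None = None, window: int = TAJIMA_WINDOW,
) -> pd.DataFrame:
    """Tajima's D in non-overlapping fixed-width windows along a chromosome."""
    positions = np.asarray(positions)
    if chrom_length is None:
        chrom_length = int(positions.max()) + 1 if positions.size else window
    rows = []
    for start in range(0, chrom_length, window):
        end = min(start + window, chrom_length)
        mask = (positions >= start) & (positions < end)
        if mask.sum() == 0:
            rows.append(TajimaWindow(chrom, start, end, 0, 0.0, float("nan")))
            continue
        D, S, pi = tajima_d(alleles[:, mask])
        rows.append(TajimaWindow(chrom, start, end, S, pi, D))
    return pd.DataFrame([vars(w) for w in rows])


def tajima_quantile_cuts(windows: pd.DataFrame, q: float = 0.05) -> dict[str, float]:
    """Per-chromosome-type 5% quantile of windowed D (X vs autosomes)."""
    cuts = {}
    is_x = windows["chrom"].astype(str).str.lstrip("chr").isin(["X"])
    for label, mask in (("autosome", ~is_x), ("X", is_x)):
        d = windows.loc[mask, "D"].dropna()
        if len(d):
            cuts[label] = float(np.quantile(d, q))
    return cuts


def fixed_te_tajima_flags(
    windows: pd.DataFrame,
    fixed_tes: Iterable,
    autosome_cut: float = AUTOSOME_TAJIMA_CUT,
    x_cut: float = X_TAJIMA_CUT,
    proximity: int = TAJIMA_PROXIMITY,
) -> set[str]:
    """Fixed TEs overlapping or near a window with significantly negative D.

    ``fixed_tes`` are TEInsertion records; a TE is flagged when at least one
    window with D below the chromosome-type cutoff overlaps the TE or lies
    within ``proximity`` bp of either TE boundary.
    """
    flagged: set[str] = set()
    win = windows.dropna(subset=["D"])
    for te in fixed_tes:
        cut = x_cut if str(te.chrom).lstrip("chr") == "X" else autosome_cut
        sub = win[(win["chrom"] == te.chrom) & (win["D"] < cut)]
        for row in sub.itertuples(index=False):
            if row.start < te.end + proximity and row.end > te.start - proximity:
                flagged.add(te.te_id)
                break
    return flagged
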