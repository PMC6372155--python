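"""Classification of TEs by recombination context, frequency, geography, location.

The screen for putatively adaptive insertions rests on a partition of the TE
complement:

* **region** — a TE sits in a high-recombination region (HRR) only when *two
  independent* recombination-rate maps both give a strictly positive rate at
  its midpoint; otherwise it is a low-recombination-region (LRR) TE, where
  linked selection makes frequency-based inference unreliable.
* **frequency class** — ``Fixed`` (> 95% in every sample with data),
  ``LowFreq`` (<= 10% in every sample), ``HighFreq`` (not fixed, and > 10% in
  at least three samples), or ``Unclassified`` for the remainder.
* **geographic class** — HighFreq TEs are subdivided by where they are at high
  frequency: the African (ancestral-range) sample only (``AF``), both Africa
  and out-of-Africa samples (``AF-OOA``), out-of-Africa only (``OOA``), or
  out-of-Africa with no African data (``NA-AF``).
* **location** — position relative to gene models (exon / UTR / first intron /
  other intron / intergenic, the latter split at 1 kb from the nearest gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel, gene_distance
from .te_frequency import SampleInfo, TEFrequencyTable, TEInsertion

REGIONS = ("LRR", "HRR")
FREQ_CLASSES = ("Fixed", "LowFreq", "HighFreq", "Unclassified")
GEO_CLASSES = ("AF", "AF-OOA", "OOA", "NA-AF", "none")
LOCATIONS = (
    "intergenic_gt1kb", "intergenic_le1kb", "exon", "UTR", "first_intron", "other_intron",
)


@dataclass(frozen=True)
class Thresholds:
    """Frequency cutoffs for the classification."""

    fixed_cut: float = 0.95
    low_cut: float = 0.10
    min_high_samples: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.fixed_cut < 1:
            raise ValueError("need 0 < low_cut < fixed_cut < 1")


@dataclass
class CategoryAssignment:
    te_id: str
    region: str = ""
    freq_class: str = ""
    geo_class: str = "none"
    location: str = ""


class RecombinationMap:
    """Two independent interval-based recombination-rate estimates (cM/Mb).

    Built from a table with columns ``chrom``, ``start``, ``end``,
    ``rate_a``, ``rate_b`` (0-based half-open intervals).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "start", "end", "rate_a", "rate_b"}
        if not required.issubset(table.columns):
            raise ValueError(f"recombination map needs columns {sorted(required)}")
        if (table[["rate_a", "rate_b"]] < 0).any().any():
            raise ValueError("recombination rates must be >= 0")
        self._by_chrom = {}
        for chrom, sub in table.groupby("chrom"):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                sub["rate_a"].to_numpy(float), sub["rate_b"].to_numpy(float),
            )

    @classmethod
    def from_tsv(cls, path) -> "RecombinationMap":
        return cls(pd.read_csv(path, sep="\t"))

    def rates(self, chrom: str, pos: int) -> tuple[float, float]:
        """Both map estimates at a position; KeyError names the missing map."""
        if chrom not in self._by_chrom:
            raise KeyError(f"maps A and B: chromosome {chrom!r} not covered")
        starts, ends, rate_a, rate_b = self._by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i < 0 or pos >= ends[i]:
            raise KeyError(f"maps A and B: position {chrom}:{pos} not covered")
        return float(rate_a[i]), float(rate_b[i])


def assign_region(te: TEInsertion, rec: RecombinationMap) -> str:
    """HRR iff both independent recombination estimates are > 0 at the TE midpoint."""
    a, b = rec.rates(te.chrom, te.midpoint)
    return "HRR" if (a > 0 and b > 0) else "LRR"


def assign_freq_class(freqs, th: Thresholds = Thresholds(), strict_high: bool = False) -> str:
    """Assign the frequency class from per-sample frequencies (NaN = missing).

    ``strict_high`` additionally requires a HighFreq TE to be below the fixed
    cutoff in *every* sample rather than merely not Fixed overall.
    """
    f = np.asarray(pd.Series(freqs).astype(float))
    f = f[~np.isnan(f)]
    if f.size == 0:
        raise ValueError("all frequencies missing")
    if np.all(f > th.fixed_cut):
        return "Fixed"
    if np.all(f <= th.low_cut):
        return "LowFreq"
    n_high = int(np.sum(f > th.low_cut))
    high_ok = n_high >= th.min_high_samples
    if strict_high:
        high_ok = high_ok and bool(np.all(f < th.fixed_cut))
    if high_ok:
        return "HighFreq"
    return "Unclassified"


def assign_geo_class(
    freqs: Mapping[str, float], sample_info: Mapping[str, SampleInfo], th: Thresholds = Thresholds()
) -> str:
    """Subdivide a HighFreq TE by where it is at high frequency.

    The African side uses the same >10% cutoff as the out-of-Africa side; the
    out-of-Africa side is "high" when at least ``th.min_high_samples`` samples
    exceed the cutoff, matching the HighFreq definition.
    """
    af_vals, ooa_vals = [], []
    for sample, f in freqs.items():
        if sample not in sample_info:
            raise KeyError(f"no sample metadata for {sample!r}")
        if f is None or (isinstance(f, float) and np.isnan(f)):
            continue
        if sample_info[sample].continent == "Africa":
            af_vals.append(f)
        else:
            ooa_vals.append(f)
    af_high = any(f > th.low_cut for f in af_vals)
    ooa_high = sum(f > th.low_cut for f in ooa_vals) >= th.min_high_samples
    if not af_vals:
        return "NA-AF" if ooa_high else "none"
    if af_high and ooa_high:
        return "AF-OOA"
    if af_high:
        return "AF"
    if ooa_high:
        return "OOA"
    return "none"


def _overlaps(te: TEInsertion, iv: tuple[int, int]) -> bool:
    return te.start < iv[1] and te.end > iv[0]


def classify_location(te: TEInsertion, genes: Sequence[GeneModel], intergenic_cut: int = 1000) -> str:
    """Locate a TE relative to gene models.

    Overlap precedence inside genes is coding exon > UTR > non-coding exon >
    intron, with introns split into the first intron of the longest annotated
    transcript vs any other intron.  Intergenic TEs are split at
    ``intergenic_cut`` bp from the nearest gene boundary.
    """
    same_chrom = [g for g in genes if g.chrom == te.chrom]
    overlapping = [g for g in same_chrom if te.start < g.end and te.end > g.start]
    if overlapping:
        in_utr = False
        in_exon = False
        first_intron = False
        other_intron = False
        for gene in overlapping:
            for tx in gene.transcripts:
                if any(_overlaps(te, iv) for iv in tx.cds):
                    return "exon"
                if any(_overlaps(te, iv) for iv in tx.utrs):
                    in_utr = True
                if any(_overlaps(te, iv) for iv in tx.exons):
                    in_exon = True
            longest = gene.longest_transcript()
            if longest is not None:
                introns = longest.introns()
                if introns and _overlaps(te, introns[0]):
                    first_intron = True
                elif any(_overlaps(te, iv) for iv in introns[1:]):
                    other_intron = True
        if in_utr:
            return "UTR"
        if in_exon:
            return "exon"
        if first_intron:
            return "first_intron"
        if other_intron:
            return "other_intron"
        return "other_intron"  # inside the gene span but not in an annotated feature
    if not same_chrom:
        return "intergenic_gt1kb"
    nearest = min(gene_distance(te, g) for g in same_chrom)
    return "intergenic_le1kb" if nearest <= intergenic_cut else "intergenic_gt1kb"


def classify_all(
    table: TEFrequencyTable,
    tes: Mapping[str, TEInsertion],
    rec: RecombinationMap | None = None,
    sample_info: Mapping[str, SampleInfo] | None = None,
    genes: Sequence[GeneModel] | None = None,
    th: Thresholds = Thresholds(),
    strict_high: bool = False,
) -> pd.DataFrame:
    """Run every classifier over a frequency table; returns one row per TE.

    Stages with missing inputs (no recombination map, no gene models, no
    sample metadata) leave the corresponding column empty rather than fail, so
    partial pipelines remain usable.
    """
    rows = []
    for te_id in table.te_ids:
        te = tes.get(te_id)
        assign = CategoryAssignment(te_id=te_id)
        freqs = table.freq.loc[te_id]
        assign.freq_class = assign_freq_class(freqs, th=th, strict_high=strict_high)
        if rec is not None and te is not None:
            assign.region = assign_region(te, rec)
        if assign.freq_class == "HighFreq" and sample_info is not None:
            assign.geo_class = assign_geo_class(freqs.to_dict(), sample_info, th=th)
        if genes is not None and te is not None:
            assign.location = classify_location(te, genes)
        rows.append(assign)
    columns = ["te_id", "region", "freq_class", "geo_class", "location"]
    out = pd.DataFrame([vars(a) for a in rows], columns=columns).set_index("te_id")
    return out
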