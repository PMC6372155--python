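"""TE population-frequency estimation from strain calls and pooled read counts.

Frequencies come from two kinds of raw evidence:

* *individual* samples: per-strain presence/absence calls (a strain genome can
  also be called ``polymorphic``, i.e. heterozygous, or ``no_data``);
* *pooled* samples: counts of reads supporting the presence and the absence of
  the insertion.

Support filters mirror standard practice for this kind of data: a per-sample
frequency is reported only when it rests on enough strains (individual mode)
or on a sane number of reads (pooled mode), and TEs typed in too few samples
are dropped altogether.  Strains carrying a chromosomal inversion near the TE
can be excluded before frequency estimation, because inversions suppress
recombination and distort local presence/absence patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: the four-state alphabet produced by the TE genotyper
CALL_STATES = ("present", "absent", "polymorphic", "no_data")

#: default support thresholds
MIN_STRAINS = 9
MIN_READS = 3
MAX_READS = 90
MIN_SAMPLES = 10

#: half-width of the inversion exclusion zone, in bp
INVERSION_WINDOW = 500_000

#: allele-copy weight of a heterozygous ("polymorphic") strain call
POLYMORPHIC_WEIGHT = 0.5


@dataclass(frozen=True)
class TEInsertion:
    """A reference TE insertion.  Coordinates are 0-based half-open."""

    te_id: str
    family: str
    order: str  # {"DNA", "LTR", "nonLTR"}
    chrom: str
    start: int
    end: int
    canonical_length: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.te_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one population sample."""

    sample_id: str
    population: str = ""
    continent: str = ""
    latitude_class: str = "none"  # {"high", "low", "none"}
    mode: str = "pooled"  # {"individual", "pooled"}
    n_strains: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "pooled"):
            raise ValueError(f"unknown sample mode {self.mode!r}")
        if self.mode == "individual" and self.n_strains < 1:
            raise ValueError("individual samples need n_strains >= 1")


@dataclass(frozen=True)
class Inversion:
    """A segregating inversion with its per-strain carrier set."""

    name: str
    chrom: str
    start: int
    end: int
    carriers: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")


@dataclass
class TEFrequencyTable:
    """TE x sample frequency matrix plus the per-cell support counts.

    ``freq`` holds fractions in [0, 1] with NaN for missing; ``support`` holds
    the number of informative strains (individual mode) or reads (pooled mode)
    behind each non-missing cell.
    """

    freq: pd.DataFrame
    support: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.freq.index.equals(self.support.index) or not self.freq.columns.equals(
            self.support.columns
        ):
            raise ValueError("freq and support matrices must be aligned")

    @property
    def te_ids(self) -> pd.Index:
        return self.freq.index

    @property
    def samples(self) -> pd.Index:
        return self.freq.columns

    def to_tsv(self, freq_path, support_path=None) -> None:
        self.freq.to_csv(freq_path, sep="\t", index_label="te_id")
        if support_path is not None:
            self.support.to_csv(support_path, sep="\t", index_label="te_id")

    @classmethod
    def from_tsv(cls, freq_path, support_path) -> "TEFrequencyTable":
        freq = pd.read_csv(freq_path, sep="\t", index_col="te_id")
        support = pd.read_csv(support_path, sep="\t", index_col="te_id")
        return cls(freq=freq, support=support)


def frequency_from_strains(
    calls: Iterable[str], min_strains: int = MIN_STRAINS, polymorphic_weight: float = POLYMORPHIC_WEIGHT
) -> tuple[float, int]:
    """Estimate a TE frequency from per-strain calls.

    Heterozygous ("polymorphic") strains contribute ``polymorphic_weight``
    allele copies.  Returns ``(frequency, n_informative)``; the frequency is
    NaN when fewer than ``min_strains`` strains carry an informative call
    (present / absent / polymorphic).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    counts = {state: 0 for state in CALL_STATES}
    for call in calls:
        if call not in counts:
            raise ValueError(f"unknown strain call {call!r}")
        counts[call] += 1
    informative = counts["present"] + counts["absent"] + counts["polymorphic"]
    if informative < min_strains:
        return float("nan"), informative
    freq = (counts["present"] + polymorphic_weight * counts["polymorphic"]) / informative
    return freq, informative


def frequency_from_pool(
    presence_reads: int, absence_reads: int, min_reads: int = MIN_READS, max_reads: int = MAX_READS
) -> tuple[float, int]:
    """Estimate a TE frequency from pooled read-support counts.

    Returns ``(frequency, total_reads)``; NaN when the read total falls
    outside ``[min_reads, max_reads]`` (too little evidence, or suspicious
    excess coverage from non-unique mapping).
    """
    if presence_reads < 0 or absence_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = presence_reads + absence_reads
    if not (min_reads <= total <= max_reads):
        return float("nan"), total
    return presence_reads / total, total


def drop_sparse_tes(table: TEFrequencyTable, min_samples: int = MIN_SAMPLES) -> TEFrequencyTable:
    """Remove TEs with a frequency estimate in fewer than ``min_samples`` samples."""
    n_obs = table.freq.notna().sum(axis=1)
    keep = n_obs >= min_samples
    dropped = table.freq.index[~keep]
    if len(dropped):
        logger.info(
            "drop_sparse_tes: removed %d TEs with < %d informative samples: %s",
            len(dropped), min_samples, ", ".join(map(str, dropped[:20])),
        )
    return TEFrequencyTable(freq=table.freq.loc[keep].copy(), support=table.support.loc[keep].copy())


def _near_inversion(te: TEInsertion, inv: Inversion, window: int) -> bool:
    if te.chrom != inv.chrom:
        return False
    return te.start < inv.end + window and te.end > inv.start - window


def inversion_corrected_frequency(
    calls: Mapping[str, str],
    te: TEInsertion,
    inversions: Sequence[Inversion],
    window: int = INVERSION_WINDOW,
    min_strains: int = MIN_STRAINS,
    polymorphic_weight: float = POLYMORPHIC_WEIGHT,
) -> tuple[float, int]:
    """Re-estimate a TE frequency after dropping inversion-carrier strains.

    A strain is removed when the TE lies inside, overlapping, or within
    ``window`` bp of any inversion carried by that strain.  The frequency is
    then recomputed from the remaining strains with the usual support filter.
    """
    excluded: set[str] = set()
    for inv in inversions:
        if _near_inversion(te, inv, window):
            excluded |= set(inv.carriers)
    kept = [call for strain, call in calls.items() if strain not in excluded]
    if not kept:
        return float("nan"), 0
    return frequency_from_strains(kept, min_strains=min_strains, polymorphic_weight=polymorphic_weight)


def build_frequency_table_individual(
    calls: pd.DataFrame, min_strains: int = MIN_STRAINS, polymorphic_weight: float = POLYMORPHIC_WEIGHT
) -> TEFrequencyTable:
    """Aggregate a long-format strain-call table into a frequency matrix.

    ``calls`` needs columns ``te_id``, ``sample``, ``strain``, ``call``.
    """
    required = {"te_id", "sample", "strain", "call"}
    if not required.issubset(calls.columns):
        raise ValueError(f"call table needs columns {sorted(required)}")
    freq_rows: dict[tuple, float] = {}
    support_rows: dict[tuple, float] = {}
    for (te_id, sample), group in calls.groupby(["te_id", "sample"], sort=True):
        f, n = frequency_from_strains(
            group["call"], min_strains=min_strains, polymorphic_weight=polymorphic_weight
        )
        freq_rows[(te_id, sample)] = f
        support_rows[(te_id, sample)] = n
    freq = pd.Series(freq_rows).unstack()
    support = pd.Series(support_rows).unstack().fillna(0)
    return TEFrequencyTable(freq=freq, support=support)


def build_frequency_table_pooled(
    counts: pd.DataFrame, min_reads: int = MIN_READS, max_reads: int = MAX_READS
) -> TEFrequencyTable:
    """Aggregate a long-format pooled-count table into a frequency matrix.

    ``counts`` needs columns ``te_id``, ``sample``, ``presence_reads``,
    ``absence_reads``.
    """
    required = {"te_id", "sample", "presence_reads", "absence_reads"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    freq_rows: dict[tuple, float] = {}
    support_rows: dict[tuple, float] = {}
    for row in counts.itertuples(index=False):
        f, n = frequency_from_pool(
            int(row.presence_reads), int(row.absence_reads), min_reads=min_reads, max_reads=max_reads
        )
        freq_rows[(row.te_id, row.sample)] = f
        support_rows[(row.te_id, row.sample)] = n
    freq = pd.Series(freq_rows).unstack()
    support = pd.Series(support_rows).unstack().fillna(0)
    return TEFrequencyTable(freq=freq, support=support)


def read_strain_calls(path) -> pd.DataFrame:
    """Read a long-format per-strain call TSV."""
    return pd.read_csv(path, sep="\t", dtype={"te_id": str, "sample": str, "strain": str})


def read_pooled_counts(path) -> pd.DataFrame:
    """Read a long-format pooled read-count TSV."""
    return pd.read_csv(path, sep="\t", dtype={"te_id": str, "sample": str})
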