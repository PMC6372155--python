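"""Category-composition and candidate-gene enrichment statistics.

Two primitives cover the enrichment questions asked of a candidate TE set:

* chi-square tests of the composition of a focal set (genomic location, TE
  order, TE family) against the background proportions, with Bonferroni
  correction across family labels;
* hypergeometric (upper-tail) tests of the overlap between genes near the
  focal TEs and curated candidate-gene lists, against a genome background.

Gene-to-TE assignment follows a promoter-scale rule: every gene within 1 kb
of the TE, or the single closest gene when none is that near.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import GeneModel, gene_distance
from .te_frequency import TEInsertion

logger = logging.getLogger(__name__)

NEARBY_DIST = 1000  # bp


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    focal_size: int
    background_size: int
    test: str  # {"chi_square", "hypergeometric"}
    statistic: float
    p_value: float
    corrected_p: float = float("nan")

    @property
    def enriched_direction(self) -> str:
        return "over" if self.observed > self.expected else "under"


def composition_test(
    focal_counts: Mapping[str, int],
    background_counts: Mapping[str, int],
    bonferroni: bool = True,
) -> list[EnrichmentResult]:
    """Per-label chi-square of focal composition vs background proportions.

    Labels must partition both sets.  Each label is tested with a 2x2
    contingency table (in/out of label x focal/background, without
    continuity correction); labels with zero background expectation are
    skipped with a warning.
    """
    labels = sorted(set(background_counts))
    if len(labels) < 2:
        raise ValueError("need at least two labels to test composition")
    unknown = set(focal_counts) - set(labels)
    if unknown:
        raise ValueError(f"focal labels missing from background: {sorted(unknown)}")
    n_focal = sum(focal_counts.values())
    n_background = sum(background_counts.values())
    results = []
    for label in labels:
        fo = focal_counts.get(label, 0)
        bo = background_counts[label]
        expected = n_focal * bo / n_background
        if expected == 0:
            logger.warning("label %s has zero background expectation; skipped", label)
            continue
        table = np.array([[fo, n_focal - fo], [bo, n_background - bo]], dtype=float)
        if min(table[0].sum(), table[1].sum()) == 0:
            continue
        if np.array_equal(table[0] / table[0].sum(), table[1] / table[1].sum()):
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        results.append(
            EnrichmentResult(
                category=label, observed=fo, expected=expected,
                focal_size=n_focal, background_size=n_background,
                test="chi_square", statistic=float(stat), p_value=float(p),
            )
        )
    if bonferroni:
        m = len(results)
        for res in results:
            res.corrected_p = min(1.0, res.p_value * m)
    return results


def candidate_gene_overlap(
    nearby_genes: Iterable[str],
    candidate_list: Iterable[str],
    background_size: int,
    category: str = "candidate_genes",
) -> EnrichmentResult:
    """Hypergeometric upper-tail test of focal-gene overlap with a curated list."""
    focal = set(nearby_genes)
    candidates = set(candidate_list)
    if not candidates:
        raise ValueError("empty candidate gene list")
    if len(focal) > background_size or len(candidates) > background_size:
        raise ValueError("set larger than the background")
    overlap = len(focal & candidates)
    # P(X >= overlap) for X ~ Hypergeom(M=background, n=|candidates|, N=|focal|)
    p = float(stats.hypergeom.sf(overlap - 1, background_size, len(candidates), len(focal)))
    expected = len(focal) * len(candidates) / background_size
    return EnrichmentResult(
        category=category, observed=overlap, expected=expected,
        focal_size=len(focal), background_size=background_size,
        test="hypergeometric", statistic=float(overlap), p_value=p,
    )


def nearest_gene_assignment(
    te: TEInsertion, genes: Sequence[GeneModel], dist: int = NEARBY_DIST
) -> tuple[list[str], bool]:
    """Genes putatively affected by a TE.

    All genes strictly closer than ``dist`` bp; when none is, the single
    closest gene on the chromosome (both, with a tie flag, when two are
    equidistant).  Returns ``(gene_ids, tie_flag)``.
    """
    same_chrom = [g for g in genes if g.chrom == te.chrom]
    if not same_chrom:
        return [], False
    with_d = [(gene_distance(te, g), g.gene_id) for g in same_chrom]
    near = sorted(gid for d, gid in with_d if d < dist)
    if near:
        return near, False
    dmin = min(d for d, _ in with_d)
    closest = sorted(gid for d, gid in with_d if d == dmin)
    if len(closest) > 1:
        logger.info("TE %s: %d equidistant nearest genes at %d bp", te.te_id, len(closest), dmin)
    return closest, len(closest) > 1


def genes_near_te_set(
    tes: Iterable[TEInsertion], genes: Sequence[GeneModel], dist: int = NEARBY_DIST
) -> set[str]:
    """Union of nearest-gene assignments over a TE set (deduplicated)."""
    out: set[str] = set()
    for te in tes:
        ids, _ = nearest_gene_assignment(te, genes, dist=dist)
        out.update(ids)
    return out


def read_candidate_lists(path) -> dict[str, set[str]]:
    """Read curated candidate-gene lists (TSV: trait, gene_id[, n_sources])."""
    table = pd.read_csv(path, sep="\t")
    if not {"trait", "gene_id"}.issubset(table.columns):
        raise ValueError("candidate list TSV needs columns trait, gene_id")
    return {trait: set(sub["gene_id"]) for trait, sub in table.groupby("trait")}
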