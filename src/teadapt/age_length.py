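"""TE age (terminal branch length) and length-ratio analyses.

Each TE family has a phylogeny of its genomic copies; the pendant-edge
(terminal branch) length of a copy, in substitutions per site, proxies the
time since its last activity.  Copies with a terminal branch shorter than
0.01 are "young".  The length ratio expresses a TE's annotated span as a
percentage of its family's canonical sequence length — long, young insertions
that are nonetheless fixed are unlikely to have fixed neutrally, because long
elements promote deleterious ectopic recombination.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

YOUNG_CUT = 0.01  # substitutions/site
LONG_RATIO_CUT = 50.0  # percent of canonical length
MIN_TE_LENGTH = 100  # bp; shorter copies misalign and are excluded upstream
MIN_FAMILY_COPIES = 3


@dataclass(frozen=True)
class TreeAge:
    te_id: str
    terminal_branch_length: float

    @property
    def age_class(self) -> str:
        return "young" if self.terminal_branch_length < YOUNG_CUT else "old"


def terminal_branch_lengths(newick: str) -> dict[str, float]:
    """Extract each leaf's pendant edge length from a Newick tree.

    Raises on duplicate leaf names or a missing pendant branch length.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf names in tree: {exc}") from None
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon is not None else None
        if name is None:
            raise ValueError("unlabeled leaf in tree")
        if name in out:
            raise ValueError(f"duplicate leaf name {name!r}")
        if leaf.edge.length is None:
            raise ValueError(f"missing branch length on pendant edge of {name!r}")
        out[name] = float(leaf.edge.length)
    return out


def ages_from_trees(
    family_trees: Mapping[str, str],
    min_copies: int = MIN_FAMILY_COPIES,
    te_lengths: Mapping[str, int] | None = None,
    min_te_length: int = MIN_TE_LENGTH,
) -> dict[str, TreeAge]:
    """Terminal-branch ages across families, skipping uninformative families.

    Families with fewer than ``min_copies`` leaves are skipped (a divergence
    estimate among so few copies is not meaningful); TEs with an annotated
    span below ``min_te_length`` bp are dropped when lengths are supplied.
    """
    ages: dict[str, TreeAge] = {}
    for family, newick in family_trees.items():
        lengths = terminal_branch_lengths(newick)
        if len(lengths) < min_copies:
            logger.warning("family %s has %d copies (< %d); skipped", family, len(lengths), min_copies)
            continue
        for te_id, tbl in lengths.items():
            if te_lengths is not None and te_lengths.get(te_id, min_te_length) < min_te_length:
                logger.info("TE %s shorter than %d bp; age not assigned", te_id, min_te_length)
                continue
            ages[te_id] = TreeAge(te_id=te_id, terminal_branch_length=tbl)
    return ages


def read_family_trees(paths: Mapping[str, str]) -> dict[str, str]:
    """Read one Newick file per family into strings."""
    return {family: io.open(path).read() for family, path in paths.items()}


def length_ratio(te) -> float:
    """TE span as a percentage of the family canonical length (>100 allowed)."""
    if te.canonical_length <= 0:
        raise ValueError(f"{te.te_id}: canonical_length must be > 0")
    return 100.0 * te.length / te.canonical_length


def young_and_long_candidates(
    fixed_te_ids: Iterable[str],
    ages: Mapping[str, TreeAge],
    ratios: Mapping[str, float],
    ratio_cut: float = LONG_RATIO_CUT,
) -> set[str]:
    """Fixed TEs that are young AND long (ratio strictly above ``ratio_cut``).

    Such insertions are candidate adaptive fixations: a young TE reached
    fixation quickly, and a long one is unlikely to have done so neutrally.
    """
    out = set()
    for te_id in fixed_te_ids:
        age = ages.get(te_id)
        ratio = ratios.get(te_id)
        if age is None or ratio is None:
            continue
        if age.age_class == "young" and ratio > ratio_cut:
            out.add(te_id)
    return out


def compare_ratio_distributions(groups: Mapping[str, Iterable[float]]) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests (plus Kruskal-Wallis) on length ratios.

    Returns a tidy frame with one row per group pair and a final
    ``kruskal_wallis`` row across all usable groups.  Groups with fewer than
    two values are skipped with a warning.
    """
    usable = {}
    for name, vals in groups.items():
        vals = list(vals)
        if len(vals) < 2:
            logger.warning("group %s has %d values; skipped", name, len(vals))
            continue
        usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need at least two usable groups")
    rows = []
    for a, b in combinations(sorted(usable), 2):
        res = stats.mannwhitneyu(usable[a], usable[b], alternative="two-sided")
        rows.append({"test": "wilcoxon_rank_sum", "group_a": a, "group_b": b,
                     "statistic": float(res.statistic), "p_value": float(res.pvalue)})
    kw = stats.kruskal(*usable.values())
    rows.append({"test": "kruskal_wallis", "group_a": "|".join(sorted(usable)), "group_b": "",
                 "statistic": float(kw.statistic), "p_value": float(kw.pvalue)})
    return pd.DataFrame(rows)
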