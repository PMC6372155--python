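"""cis-eQTL scan: TE genotype vs expression of nearby genes.

Per-strain TE calls are coded additively (absent = 0, polymorphic = 1,
present = 2, no data = missing) and regressed against normalized expression
of every gene whose span lies within 1 kb of either TE junction, separately
for female and male expression panels.  P-values come from the ordinary
least-squares t test on the slope; Benjamini-Hochberg FDR is applied within
each sex across all tested pairs.  At the reporting level a TE counts as
"significant" when raw p < 0.05 in at least one sex, with the FDR < 0.05
subset reported separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CIS_DIST = 1000  # bp, strict: gene must be < 1 kb from a TE junction
GENOTYPE_CODE = {"absent": 0.0, "polymorphic": 1.0, "present": 2.0, "no_data": math.nan}

#: DGRP-style frequency classes used in the contingency summary
EQTL_FREQ_CLASSES = ("HighFreq", "Fixed", "LowFreq", "Private")


@dataclass
class EqtlResult:
    te_id: str
    gene_id: str
    sex: str
    beta: float
    t_stat: float
    p_value: float
    n: int
    fdr: float = float("nan")

    @property
    def direction(self) -> str:
        return "positive" if self.beta > 0 else "negative"


def genotype_coding(call: str) -> float:
    """Additive 0/1/2 coding of a per-strain TE call (no data -> NaN)."""
    try:
        return GENOTYPE_CODE[call]
    except KeyError:
        raise ValueError(f"unknown TE call {call!r}") from None


def cis_pairs(tes: Sequence, genes: Sequence, cis_dist: int = CIS_DIST) -> list[tuple[str, str]]:
    """(te_id, gene_id) pairs with gene span < ``cis_dist`` bp from a TE junction.

    Both TE junction coordinates (start and end) are tested against the gene
    span; an overlap counts as distance zero.
    """
    pairs = []
    for te in tes:
        for gene in genes:
            if gene.chrom != te.chrom:
                continue
            d = min(_point_span_distance(te.start, gene), _point_span_distance(te.end, gene))
            if d < cis_dist:
                pairs.append((te.te_id, gene.gene_id))
    return pairs


def _point_span_distance(pos: int, gene) -> int:
    if pos < gene.start:
        return gene.start - pos
    if pos > gene.end:
        return pos - gene.end
    return 0


def fit_pair(
    genotypes: Sequence[float], expression: Sequence[float], sex: str,
    te_id: str = "", gene_id: str = "",
) -> EqtlResult | None:
    """OLS of expression on additive TE genotype for one (TE, gene, sex).

    Strains missing either value are dropped pairwise.  Returns None (with a
    log line) when fewer than three complete strains remain or the genotype
    is constant among them.
    """
    g = np.asarray(genotypes, dtype=float)
    e = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(e))
    g, e = g[ok], e[ok]
    if g.size < 3:
        logger.info("pair (%s, %s, %s): only %d complete strains; skipped", te_id, gene_id, sex, g.size)
        return None
    if np.all(g == g[0]):
        logger.info("pair (%s, %s, %s): constant genotype; skipped", te_id, gene_id, sex)
        return None
    fit = stats.linregress(g, e)
    se = fit.stderr
    t = fit.slope / se if se > 0 else math.copysign(math.inf, fit.slope)
    return EqtlResult(
        te_id=te_id, gene_id=gene_id, sex=sex,
        beta=float(fit.slope), t_stat=float(t), p_value=float(fit.pvalue), n=int(g.size),
    )


def scan(
    genotype: pd.DataFrame,
    expression: Mapping[str, pd.DataFrame],
    pairs: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Fit every cis pair in every sex and attach within-sex BH FDR.

    ``genotype`` is TE x strain (0/1/2/NaN); ``expression`` maps sex to a
    gene x strain frame.  Strain columns are aligned by intersection.
    """
    results: list[EqtlResult] = []
    for sex, expr in expression.items():
        strains = genotype.columns.intersection(expr.columns)
        for te_id, gene_id in pairs:
            if te_id not in genotype.index or gene_id not in expr.index:
                continue
            res = fit_pair(
                genotype.loc[te_id, strains], expr.loc[gene_id, strains], sex,
                te_id=te_id, gene_id=gene_id,
            )
            if res is not None:
                results.append(res)
    frame = pd.DataFrame([vars(r) | {"direction": r.direction} for r in results])
    if frame.empty:
        return frame
    for sex in frame["sex"].unique():
        mask = frame["sex"] == sex
        frame.loc[mask, "fdr"] = multipletests(frame.loc[mask, "p_value"], method="fdr_bh")[1]
    return frame


def significant_tes(
    results: pd.DataFrame, alpha: float = 0.05, use_fdr: bool = False
) -> pd.DataFrame:
    """Per-TE significance summary across sexes.

    A TE is significant when its best pair reaches ``alpha`` (raw p by
    default, BH FDR with ``use_fdr``) in at least one sex; the direction is
    the sign of the best pair's slope, and positive/negative flags record
    whether any significant pair has that sign.
    """
    col = "fdr" if use_fdr else "p_value"
    rows = []
    for te_id, sub in results.groupby("te_id"):
        sig = sub[sub[col] < alpha]
        best = sub.loc[sub[col].idxmin()]
        rows.append({
            "te_id": te_id,
            "significant": len(sig) > 0,
            "any_positive": bool((sig["beta"] > 0).any()),
            "any_negative": bool((sig["beta"] < 0).any()),
            "best_p": float(best[col]),
            "best_beta": float(best["beta"]),
        })
    return pd.DataFrame(rows).set_index("te_id")


def dgrp_freq_class(freq: float, n_carriers: int | None = None) -> str:
    """Frequency class in a single (DGRP-like) panel.

    Fixed >= 95%, LowFreq <= 10% (Private when exactly one carrier strain),
    HighFreq in between.
    """
    if math.isnan(freq):
        raise ValueError("missing frequency")
    if freq >= 0.95:
        return "Fixed"
    if freq <= 0.10:
        return "Private" if n_carriers == 1 else "LowFreq"
    return "HighFreq"


def frequency_enrichment_table(
    significant: Iterable[str], analyzed_classes: Mapping[str, str],
    subsets: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Contingency summary of eQTL hits by TE frequency class.

    Rows: the analyzed background and the significant set (plus optional
    extra subsets, e.g. positive/negative correlations or an FDR cut); one
    column pair (count, percent) per frequency class.  A chi-square
    goodness-of-fit p against the analyzed-class proportions is attached per
    row (Private is folded into LowFreq for the test to keep classes
    disjoint).
    """
    analyzed = pd.Series(analyzed_classes)
    all_sets = {"analyzed": list(analyzed.index), "significant": list(significant)}
    if subsets:
        all_sets.update({k: list(v) for k, v in subsets.items()})
    rows = {}
    for name, ids in all_sets.items():
        classes = analyzed.reindex(ids).dropna()
        counts = classes.value_counts().reindex(EQTL_FREQ_CLASSES, fill_value=0)
        # Private is reported as a subset of LowFreq, not a disjoint class
        counts["LowFreq"] += counts["Private"]
        total = counts[["HighFreq", "Fixed", "LowFreq"]].sum()
        row: dict[str, float] = {}
        for cls in EQTL_FREQ_CLASSES:
            row[f"{cls}_n"] = int(counts[cls])
            row[f"{cls}_pct"] = 100.0 * counts[cls] / total if total else 0.0
        row["total"] = int(total)
        rows[name] = row
    out = pd.DataFrame(rows).T
    # goodness-of-fit vs analyzed proportions, disjoint classes
    def fold(counts):
        return np.array([
            counts["HighFreq_n"], counts["Fixed_n"], counts["LowFreq_n"],
        ], dtype=float)
    base = fold(out.loc["analyzed"])
    base_prop = base / base.sum()
    pvals = {}
    for name in out.index:
        obs = fold(out.loc[name])
        if name == "analyzed" or obs.sum() == 0:
            pvals[name] = float("nan")
            continue
        expected = base_prop * obs.sum()
        stat, p = stats.chisquare(obs, f_exp=expected)
        pvals[name] = float(p)
    out["chi2_p_vs_analyzed"] = pd.Series(pvals)
    return out
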