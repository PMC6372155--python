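"""End-to-end orchestration of the adaptive-TE screen.

``run_all`` executes the stage sequence on a workspace of input files:

1. TE frequency estimation (strain calls and/or pooled read counts),
2. classification (recombination region, frequency class, geography,
   genomic location),
3. age and length-ratio analysis with the young-and-long rule for fixed TEs,
4. haplotype sweep scans (iHS, nSL, H12) with empirical neutral nulls,
5. FST population differentiation with latitude concordance, and windowed
   Tajima's D around fixed TEs,
6. the evidence union into a per-TE candidate table,
7. cis-eQTL scan and enrichment statistics for the candidate set.

Every stage logs its input/output counts; a failure aborts the run naming
the stage.  ``demo`` generates a complete synthetic workspace with a planted
sweep and planted expression effects, then runs the full pipeline on it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (age_length, annotations, classification, enrichment, eqtl,
               freq_stats, sweep_scan, synthetic_data, te_frequency)
from .te_frequency import SampleInfo, TEFrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (YAML-serializable)."""

    output_dir: str = "teadapt_run"
    seed: int = 0
    # inputs
    calls_tsv: str | None = None          # per-strain TE calls (individual samples)
    pooled_tsv: str | None = None         # pooled read counts
    samples_tsv: str | None = None        # sample metadata
    te_bed: str | None = None
    recombination_tsv: str | None = None
    trees_tsv: str | None = None          # family <tab> newick
    sweep_vcf: str | None = None          # phased haplotype panel with NEUT flags
    sweep_states_tsv: str | None = None   # per-strain TE calls for the sweep panel
    fst_pairs_tsv: str | None = None      # pair, sample_a, sample_b, side_a, side_b, null_vcf
    gff: str | None = None
    expr_female_tsv: str | None = None
    expr_male_tsv: str | None = None
    eqtl_genotypes_tsv: str | None = None  # TE x strain additive coding
    candidate_genes_tsv: str | None = None
    african_sample: str | None = None
    # parameters
    min_strains: int = te_frequency.MIN_STRAINS
    min_reads: int = te_frequency.MIN_READS
    max_reads: int = te_frequency.MAX_READS
    min_samples: int = te_frequency.MIN_SAMPLES
    fixed_cut: float = 0.95
    low_cut: float = 0.10
    min_high_samples: int = 3
    h12_window: int = sweep_scan.H12_WINDOW
    ehh_floor: float = sweep_scan.EHH_FLOOR
    null_max_sites: int | None = 400
    sweep_alpha: float = 0.05
    h12_top_fraction: float = sweep_scan.H12_TOP_FRACTION
    tests: tuple = ("ihs", "nsl", "h12")

    def thresholds(self) -> classification.Thresholds:
        return classification.Thresholds(
            fixed_cut=self.fixed_cut, low_cut=self.low_cut, min_high_samples=self.min_high_samples
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "tests" in raw:
            raw["tests"] = tuple(raw["tests"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _read_samples(path) -> dict[str, SampleInfo]:
    table = pd.read_csv(path, sep="\t")
    out = {}
    for row in table.itertuples(index=False):
        out[row.sample_id] = SampleInfo(
            sample_id=row.sample_id, population=getattr(row, "population", ""),
            continent=getattr(row, "continent", ""),
            latitude_class=getattr(row, "latitude_class", "none"),
            mode=getattr(row, "mode", "pooled"), n_strains=int(getattr(row, "n_strains", 0)),
        )
    return out


def _te_states_to_haplotypes(states: pd.Series, strains: list[str]) -> np.ndarray:
    """Expand per-strain presence/absence calls to per-haplotype marker states."""
    per_hap = []
    for strain in strains:
        call = states.get(strain, "no_data")
        if call == "present":
            per_hap += [1, 1]
        elif call == "absent":
            per_hap += [0, 0]
        else:  # polymorphic phase unknown, no_data
            per_hap += [sweep_scan.MISSING, sweep_scan.MISSING]
    return np.array(per_hap, dtype=np.int8)


def run_all(config: RunConfig) -> dict:
    """Execute the full stage sequence; returns the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"counts": {}, "outputs": {}, "seed": config.seed}
    config.to_yaml(out / "run_config.yaml")
    log_handler = logging.FileHandler(out / "run.log")
    logging.getLogger("teadapt").addHandler(log_handler)
    try:
        # ---- stage: te_frequency -------------------------------------------------
        stage = "te_frequency"
        try:
            tables = []
            if config.calls_tsv:
                calls = te_frequency.read_strain_calls(config.calls_tsv)
                tables.append(te_frequency.build_frequency_table_individual(
                    calls, min_strains=config.min_strains))
            if config.pooled_tsv:
                counts = te_frequency.read_pooled_counts(config.pooled_tsv)
                tables.append(te_frequency.build_frequency_table_pooled(
                    counts, min_reads=config.min_reads, max_reads=config.max_reads))
            if not tables:
                raise ValueError("no TE observation inputs configured")
            freq = pd.concat([t.freq for t in tables], axis=1)
            support = pd.concat([t.support for t in tables], axis=1).fillna(0)
            table = TEFrequencyTable(freq=freq, support=support)
            report["counts"]["tes_input"] = len(table.te_ids)
            table = te_frequency.drop_sparse_tes(table, min_samples=config.min_samples)
            report["counts"]["tes_after_sparse_filter"] = len(table.te_ids)
            table.to_tsv(out / "te_frequencies.tsv", out / "te_support.tsv")
            report["outputs"]["te_frequencies"] = str(out / "te_frequencies.tsv")
        except Exception as exc:  # noqa: BLE001 - any stage error aborts with the stage name
            raise StageError(stage, str(exc)) from exc

        # ---- stage: classification ----------------------------------------------
        stage = "classification"
        try:
            if not config.recombination_tsv:
                raise ValueError("missing recombination map")
            recmap = classification.RecombinationMap.from_tsv(config.recombination_tsv)
            tes = {te.te_id: te for te in annotations.read_te_bed(config.te_bed)}
            samples = _read_samples(config.samples_tsv) if config.samples_tsv else None
            genes = annotations.read_gff3(config.gff) if config.gff else None
            classes = classification.classify_all(
                table, tes, rec=recmap, sample_info=samples, genes=genes, th=config.thresholds()
            )
            classes.to_csv(out / "te_classes.tsv", sep="\t")
            report["outputs"]["te_classes"] = str(out / "te_classes.tsv")
            for col in ("region", "freq_class"):
                report["counts"][col] = classes[col].value_counts().to_dict()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        hrr = classes[classes["region"] == "HRR"]
        fixed_hrr = set(hrr[hrr["freq_class"] == "Fixed"].index)
        high_hrr = set(hrr[hrr["freq_class"] == "HighFreq"].index)

        # ---- stage: age_length ---------------------------------------------------
        stage = "age_length"
        young_long: set[str] = set()
        try:
            if config.trees_tsv:
                trees = pd.read_csv(config.trees_tsv, sep="\t")
                ages = age_length.ages_from_trees(
                    dict(zip(trees["family"], trees["newick"])),
                    te_lengths={t.te_id: t.length for t in tes.values()},
                )
                ratios = {
                    te_id: age_length.length_ratio(te)
                    for te_id, te in tes.items() if te.canonical_length > 0
                }
                age_table = pd.DataFrame({
                    "terminal_branch_length": {k: v.terminal_branch_length for k, v in ages.items()},
                    "age_class": {k: v.age_class for k, v in ages.items()},
                    "length_ratio": pd.Series(ratios),
                })
                age_table.to_csv(out / "te_age_length.tsv", sep="\t", index_label="te_id")
                report["outputs"]["te_age_length"] = str(out / "te_age_length.tsv")
                young_long = age_length.young_and_long_candidates(fixed_hrr, ages, ratios)
                report["counts"]["young_and_long"] = len(young_long)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: sweep_scan ---------------------------------------------------
        stage = "sweep_scan"
        sweep_flags = pd.DataFrame()
        try:
            if config.sweep_vcf and config.sweep_states_tsv:
                sweep_flags = _sweep_stage(config, tes, out)
                report["counts"]["tes_sweep_scanned"] = len(sweep_flags)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: freq_stats ---------------------------------------------------
        stage = "freq_stats"
        fst_concordant: set[str] = set()
        tajima_flagged: set[str] = set()
        try:
            if config.fst_pairs_tsv:
                fst_concordant = _fst_stage(config, table, samples, out)
                report["counts"]["fst_concordant"] = len(fst_concordant)
            if config.sweep_vcf:
                tajima_flagged = _tajima_stage(config, tes, fixed_hrr, out)
                report["counts"]["tajima_flagged"] = len(tajima_flagged)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: evidence_union ----------------------------------------------
        stage = "evidence_union"
        try:
            candidates = evidence_union(
                classes, sweep_flags, fst_concordant, young_long, tajima_flagged
            )
            candidates.to_csv(out / "candidates.tsv", sep="\t")
            report["outputs"]["candidates"] = str(out / "candidates.tsv")
            report["counts"]["candidates"] = int(candidates["candidate"].sum())
            report["counts"]["high_freq_evaluable"] = int(
                candidates.loc[candidates["freq_class"] == "HighFreq", "any_test_computed"].sum()
            )
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: eqtl -----------------------------------------------------------
        stage = "eqtl"
        try:
            if config.eqtl_genotypes_tsv and config.expr_female_tsv and config.gff:
                geno = pd.read_csv(config.eqtl_genotypes_tsv, sep="\t", index_col=0)
                expr = {"female": pd.read_csv(config.expr_female_tsv, sep="\t", index_col=0)}
                if config.expr_male_tsv:
                    expr["male"] = pd.read_csv(config.expr_male_tsv, sep="\t", index_col=0)
                pairs = eqtl.cis_pairs(list(tes.values()), genes or [])
                results = eqtl.scan(geno, expr, pairs)
                results.to_csv(out / "eqtl_results.tsv", sep="\t", index=False)
                report["outputs"]["eqtl_results"] = str(out / "eqtl_results.tsv")
                if not results.empty:
                    sig = eqtl.significant_tes(results)
                    report["counts"]["eqtl_significant_tes"] = int(sig["significant"].sum())
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: enrichment -----------------------------------------------------
        stage = "enrichment"
        try:
            if genes is not None:
                focal_tes = [tes[t] for t in candidates.index[candidates["candidate"]] if t in tes]
                focal_genes = enrichment.genes_near_te_set(focal_tes, genes)
                rows = []
                focal_orders = pd.Series([tes[t].order for t in high_hrr if t in tes]).value_counts()
                background_orders = pd.Series([t.order for t in tes.values()]).value_counts()
                if len(background_orders) >= 2 and focal_orders.sum() > 0:
                    for res in enrichment.composition_test(
                        focal_orders.to_dict(), background_orders.to_dict()
                    ):
                        rows.append(vars(res) | {"set": "highfreq_order"})
                if config.candidate_genes_tsv and focal_genes:
                    lists = enrichment.read_candidate_lists(config.candidate_genes_tsv)
                    for trait, gene_set in lists.items():
                        res = enrichment.candidate_gene_overlap(
                            focal_genes, gene_set, background_size=len(genes), category=trait
                        )
                        rows.append(vars(res) | {"set": "candidate_genes"})
                if rows:
                    pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
                    report["outputs"]["enrichment"] = str(out / "enrichment.tsv")
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        report["runtime_s"] = round(time.time() - t0, 2)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        logger.info("pipeline finished in %.1f s", report["runtime_s"])
        return report
    finally:
        logging.getLogger("teadapt").removeHandler(log_handler)


def _sweep_stage(config: RunConfig, tes, out: Path) -> pd.DataFrame:
    """iHS / nSL / H12 at every TE embedded in the sweep panel, with nulls."""
    hap = sweep_scan.HaplotypeMatrix.from_vcf(config.sweep_vcf)
    states = pd.read_csv(config.sweep_states_tsv, sep="\t")
    import cyvcf2

    strains = list(cyvcf2.VCF(str(config.sweep_vcf)).samples)
    rng = np.random.default_rng(config.seed)
    neutral = sweep_scan.neutral_statistics(
        hap, tests=config.tests, max_sites=config.null_max_sites, rng=rng,
        h12_snp_window=config.h12_window, ehh_floor=config.ehh_floor,
    )
    nulls = {}
    if "ihs" in config.tests:
        nulls["ihs"] = sweep_scan.NullDistribution(
            "ihs", neutral["ihs_unstd"], neutral["freq"], n_bins=sweep_scan.IHS_BINS, binning="width")
    if "nsl" in config.tests:
        nulls["nsl"] = sweep_scan.NullDistribution(
            "nsl", neutral["nsl_unstd"], neutral["freq"], n_bins=sweep_scan.NSL_BINS, binning="count")
    if "h12" in config.tests:
        nulls["h12"] = sweep_scan.NullDistribution("h12", neutral["h12"].dropna())
    lo, hi = hap.positions.min(), hap.positions.max()
    rows = []
    for te_id, sub in states.groupby("te_id"):
        te = tes.get(te_id)
        if te is None or not (lo <= te.midpoint <= hi):
            continue
        marker = _te_states_to_haplotypes(sub.set_index("strain")["call"], strains)
        embedded, site = sweep_scan.embed_te_marker(hap, marker, te.midpoint)
        row: dict = {"te_id": te_id, "site": site, "freq": embedded.derived_frequency(site)}
        if "ihs" in config.tests:
            try:
                res = sweep_scan.ihs(embedded, site, ehh_floor=config.ehh_floor,
                                     standardization=nulls["ihs"])
                row["ihs_std"] = res.std
                row["ihs_sig"] = bool(sweep_scan.flag_ihs_nsl(
                    {te_id: res.std}, nulls["ihs"], alpha=config.sweep_alpha).get(te_id, False))
            except ValueError:
                row["ihs_std"], row["ihs_sig"] = float("nan"), None
        if "nsl" in config.tests:
            try:
                nomiss = embedded.drop_missing()
                ns = int(np.searchsorted(nomiss.positions, embedded.positions[site]))
                if ns >= nomiss.n_sites or nomiss.positions[ns] != embedded.positions[site]:
                    raise ValueError("marker pruned")
                res = sweep_scan.nsl(nomiss, ns, standardization=nulls["nsl"])
                row["nsl_std"] = res.std
                row["nsl_sig"] = bool(sweep_scan.flag_ihs_nsl(
                    {te_id: res.std}, nulls["nsl"], alpha=config.sweep_alpha).get(te_id, False))
            except ValueError:
                row["nsl_std"], row["nsl_sig"] = float("nan"), None
        if "h12" in config.tests:
            try:
                res = sweep_scan.h12_window(embedded, site, window=config.h12_window,
                                            te_states=marker)
                row["h12"] = res.h12
                row["h12_sig"] = sweep_scan.flag_h12(
                    {te_id: res}, nulls["h12"], top_fraction=config.h12_top_fraction)[te_id]
            except ValueError:
                row["h12"], row["h12_sig"] = float("nan"), None
        rows.append(row)
    flags = pd.DataFrame(rows).set_index("te_id") if rows else pd.DataFrame()
    flags.to_csv(out / "sweep_results.tsv", sep="\t")
    return flags


def _fst_stage(config: RunConfig, table: TEFrequencyTable, samples, out: Path) -> set[str]:
    """Pairwise WC84 FST for TEs with stratified neutral nulls and concordance."""
    # keep_default_na: "NA" is a legitimate pair label (North America), not NaN
    pairs = pd.read_csv(config.fst_pairs_tsv, sep="\t", keep_default_na=False)
    african = None
    if config.african_sample and config.african_sample in table.freq.columns:
        african = table.freq[config.african_sample]
    records = []
    all_rows = []
    for spec_row in pairs.itertuples(index=False):
        null_hap = sweep_scan.HaplotypeMatrix.from_vcf(spec_row.null_vcf)
        demes = np.zeros(null_hap.n_haplotypes, dtype=int)
        demes[null_hap.n_haplotypes // 2:] = 1
        null_theta = {"AF_high": [], "AF_low": []}
        for site in np.flatnonzero(null_hap.neutral):
            col = null_hap.alleles[:, site]
            n0, n1 = (demes == 0).sum(), (demes == 1).sum()
            res = freq_stats.wc_fst(n0, int(col[demes == 0].sum()), n1, int(col[demes == 1].sum()))
            if not res.defined:
                continue
            af_freq = col[demes == 0].mean()  # source deme stands in for the ancestral range
            stratum = "AF_high" if af_freq > freq_stats.AFRICAN_HIGH_CUT else "AF_low"
            null_theta[stratum].append(res.theta)
        te_theta, af_map = {}, {}
        sides = {spec_row.sample_a: spec_row.side_a, spec_row.sample_b: spec_row.side_b}
        for te_id in table.te_ids:
            fa = table.freq.at[te_id, spec_row.sample_a]
            fb = table.freq.at[te_id, spec_row.sample_b]
            if np.isnan(fa) or np.isnan(fb):
                continue
            n_st = 20
            na, da = freq_stats.pooled_pseudocounts(
                fa, n_st, int(table.support.at[te_id, spec_row.sample_a]))
            nb, db = freq_stats.pooled_pseudocounts(
                fb, n_st, int(table.support.at[te_id, spec_row.sample_b]))
            res = freq_stats.wc_fst(na, da, nb, db, pair=(spec_row.sample_a, spec_row.sample_b),
                                    locus_id=te_id)
            if not res.defined:
                continue
            te_theta[te_id] = res.theta
            if african is not None:
                af_map[te_id] = african.get(te_id, float("nan"))
            else:
                af_map[te_id] = 0.0  # no ancestral data: single low stratum
            all_rows.append({"te_id": te_id, "pair": spec_row.pair, "theta": res.theta,
                             "direction": res.direction})
        flags = freq_stats.fst_significance(te_theta, null_theta, af_map)
        for te_id, sig in flags.items():
            direction = next(r["direction"] for r in all_rows
                             if r["te_id"] == te_id and r["pair"] == spec_row.pair)
            records.append({"te_id": te_id, "pair": spec_row.pair, "significant": sig,
                            "high_side": sides.get(direction, "none")})
    pd.DataFrame(all_rows).to_csv(out / "fst_results.tsv", sep="\t", index=False)
    if not records:
        return set()
    rec_frame = pd.DataFrame(records)
    rec_frame.to_csv(out / "fst_concordance.tsv", sep="\t", index=False)
    return freq_stats.concordance_filter(rec_frame)


def _tajima_stage(config: RunConfig, tes, fixed_hrr: set[str], out: Path) -> set[str]:
    hap = sweep_scan.HaplotypeMatrix.from_vcf(config.sweep_vcf)
    alleles = np.where(hap.alleles == sweep_scan.MISSING, 0, hap.alleles)
    windows = freq_stats.tajima_windows(alleles, hap.positions, hap.chrom)
    windows.to_csv(out / "tajima_windows.tsv", sep="\t", index=False)
    fixed = [tes[t] for t in fixed_hrr if t in tes]
    return freq_stats.fixed_te_tajima_flags(windows, fixed)


def evidence_union(
    classes: pd.DataFrame,
    sweep_flags: pd.DataFrame,
    fst_concordant: set[str],
    young_long: set[str],
    tajima_flagged: set[str],
) -> pd.DataFrame:
    """Join all selection evidence into the per-TE candidate table.

    Polymorphic candidates are HighFreq TEs with at least one significant
    test (sweep or concordant FST); fixed candidates are Fixed TEs that are
    young-and-long or near a significantly negative Tajima's D window.
    """
    frame = classes.copy()
    for col in ("ihs_sig", "nsl_sig", "h12_sig"):
        if col in sweep_flags.columns:
            frame[col] = sweep_flags[col].reindex(frame.index)
        else:
            frame[col] = None
    frame["fst_concordant"] = [t in fst_concordant for t in frame.index]
    frame["young_and_long"] = [t in young_long for t in frame.index]
    frame["tajima"] = [t in tajima_flagged for t in frame.index]
    sweep_any = (frame[["ihs_sig", "nsl_sig", "h12_sig"]] == True).any(axis=1)  # noqa: E712
    frame["any_test_computed"] = (
        frame[["ihs_sig", "nsl_sig", "h12_sig"]].notna().any(axis=1) | frame["fst_concordant"]
    )
    poly_candidate = (frame["freq_class"] == "HighFreq") & (sweep_any | frame["fst_concordant"])
    fixed_candidate = (frame["freq_class"] == "Fixed") & (frame["young_and_long"] | frame["tajima"])
    frame["candidate"] = poly_candidate | fixed_candidate
    return frame


# ---------------------------------------------------------------------------
# recovery benchmark
# ---------------------------------------------------------------------------

def _focal_statistics(hap: sweep_scan.HaplotypeMatrix, site: int) -> dict:
    row = {}
    for name, fn in (("ihs", lambda: sweep_scan.ihs(hap, site).unstd),
                     ("nsl", lambda: sweep_scan.nsl(hap, site).unstd),
                     ("h12", lambda: sweep_scan.h12_window(hap, site).h12)):
        try:
            row[name] = fn()
        except ValueError:
            row[name] = float("nan")
    return row


def sweep_recovery_rates(
    seed: int = 0, n_sweep: int = 100, n_neutral: int = 200, n_null: int = 25,
    s: float = 0.1, target_range: tuple[float, float] = (0.4, 0.8),
    config_kw: dict | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-test flag rates at the focal TE for sweep vs neutral replicates.

    Hard-sweep replicates plant a selected TE marker (selection coefficient
    ``s``) and ask whether each statistic flags it against an empirical null
    built from the neutral SNPs of ``n_null`` independent neutral replicates
    run under identical conditions.  The false-positive rate is measured the
    same way on neutral replicates, with a random segregating site of
    sweep-like frequency standing in for a neutral TE marker (a neutral
    insertion is genealogically exchangeable with any neutral variant of the
    same frequency).  Returns ``(power, fpr)`` as per-test Series.
    """
    base = int(np.random.default_rng(seed).integers(1, 2**30))
    kw = config_kw or {}
    frames = []
    for k in range(n_null):
        cfg = synthetic_data.SimConfig(sweep_kind="none", seed=base + k, **kw)
        hap, _ = synthetic_data.simulate_population(cfg)
        frames.append(sweep_scan.neutral_statistics(
            hap, max_sites=60, rng=np.random.default_rng(base + k)))
    neut = pd.concat(frames, ignore_index=True)
    nulls = {
        "ihs": sweep_scan.NullDistribution(
            "ihs", neut["ihs_unstd"], neut["freq"], n_bins=sweep_scan.IHS_BINS),
        "nsl": sweep_scan.NullDistribution(
            "nsl", neut["nsl_unstd"], neut["freq"], n_bins=sweep_scan.NSL_BINS,
            binning="count"),
        "h12": sweep_scan.NullDistribution("h12", neut["h12"].dropna()),
    }

    def flags_for(hap, site):
        freq = hap.derived_frequency(site)
        row = _focal_statistics(hap, site)
        out = {}
        for stat in ("ihs", "nsl"):
            z = nulls[stat].standardize([row[stat]], [freq])[0]
            out[stat] = bool(abs(z) > nulls[stat].abs_threshold(0.05)) \
                if not np.isnan(z) else False
        out["h12"] = bool(row["h12"] > nulls["h12"].upper_threshold(0.15)) \
            if not np.isnan(row["h12"]) else False
        return out

    # power: planted hard sweeps, tested at the focal marker; the frequency
    # the sweep is caught at varies across replicates
    power_rows = []
    target_rng = np.random.default_rng(base + 1)
    k = attempt = 0
    while k < n_sweep and attempt < 4 * n_sweep:
        cfg = synthetic_data.SimConfig(
            sweep_kind="hard", selection_coefficient=s, seed=base + 10_000 + attempt,
            target_frequency=float(target_rng.uniform(*target_range)), **kw)
        attempt += 1
        hap, truth = synthetic_data.simulate_population(cfg)
        freq = hap.derived_frequency(truth.sweep_site)
        if not 0.05 < freq < 0.95:
            continue
        power_rows.append(flags_for(hap, truth.sweep_site))
        k += 1

    # false positives: random segregating sites of sweep-like frequency in
    # fresh neutral replicates stand in for neutral TE markers.  Candidate
    # sites are pooled across replicates before sampling, so replicates enter
    # with the same weight they carry in the null (one site, one draw).
    n_fpr_reps = max(10, n_neutral // 10)
    reps = []
    pool: list[tuple[int, int]] = []
    for k in range(n_fpr_reps):
        cfg = synthetic_data.SimConfig(sweep_kind="none", seed=base + 50_000 + k, **kw)
        hap, truth = synthetic_data.simulate_population(cfg)
        reps.append(hap)
        freqs = hap.alleles.mean(axis=0)
        eligible = np.flatnonzero(~hap.neutral & (freqs > 0.4) & (freqs < 0.9))
        pool.extend((k, int(s)) for s in eligible if s != truth.sweep_site)
    rng = np.random.default_rng(base + 60_000)
    picks = rng.choice(len(pool), size=min(n_neutral, len(pool)), replace=False)
    fpr_rows = [flags_for(reps[pool[i][0]], pool[i][1]) for i in picks]
    return pd.DataFrame(power_rows).mean(), pd.DataFrame(fpr_rows).mean()


# ---------------------------------------------------------------------------
# demo workspace
# ---------------------------------------------------------------------------

def demo(output_dir: str = "teadapt_demo", seed: int = 0, n_tes: int = 80) -> dict:
    """Generate a synthetic workspace with planted signals and run the pipeline.

    The workspace contains one African and five out-of-Africa samples, a TE
    panel with fixed / high / low archetypes, a phased sweep panel in which
    one HighFreq TE rides a planted hard sweep, two FST population pairs,
    and expression with planted cis effects.  Returns the run report with
    the ground truth attached under ``"truth"``.
    """
    out = Path(output_dir).resolve()  # configs must survive a cwd change
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    samples = ["AF", "EU1", "EU2", "NA1", "NA2", "OC1"]
    tes, freq_table = synthetic_data.simulate_te_panel(n_tes, samples, rng)

    # observations: one individually sequenced sample plus pooled samples
    indiv = synthetic_data.emit_te_observations(
        freq_table[samples[:1]], "individual", n_strains=15, rng=rng)
    pooled = synthetic_data.emit_te_observations(
        freq_table[samples[1:]], "pooled", coverage=60, rng=rng)
    indiv.to_csv(out / "inputs" / "calls_individual.tsv", sep="\t", index=False)
    pooled.to_csv(out / "inputs" / "counts_pooled.tsv", sep="\t", index=False)

    sample_meta = pd.DataFrame([
        {"sample_id": "AF", "population": "Zambia", "continent": "Africa",
         "latitude_class": "low", "mode": "individual", "n_strains": 15},
        {"sample_id": "EU1", "population": "Sweden", "continent": "Europe",
         "latitude_class": "high", "mode": "pooled", "n_strains": 30},
        {"sample_id": "EU2", "population": "Italy", "continent": "Europe",
         "latitude_class": "low", "mode": "pooled", "n_strains": 30},
        {"sample_id": "NA1", "population": "Maine", "continent": "NorthAmerica",
         "latitude_class": "high", "mode": "pooled", "n_strains": 30},
        {"sample_id": "NA2", "population": "Florida", "continent": "NorthAmerica",
         "latitude_class": "low", "mode": "pooled", "n_strains": 30},
        {"sample_id": "OC1", "population": "Yering", "continent": "Oceania",
         "latitude_class": "high", "mode": "pooled", "n_strains": 30},
    ])
    sample_meta.to_csv(out / "inputs" / "samples.tsv", sep="\t", index=False)

    chrom_length = 20_000_000
    recmap = synthetic_data.make_recombination_map("2L", chrom_length, rng)
    recmap.to_csv(out / "inputs" / "recmap.tsv", sep="\t", index=False)

    # sweep panel: a hard sweep planted at one HighFreq TE
    cfg = synthetic_data.SimConfig(
        n_haplotypes=120, n_sites=500, sequence_length=30_000,
        selection_coefficient=0.1, sweep_kind="hard", focal_position=15_000,
        target_frequency=0.6, neutral_fraction=0.6, mutation_rate=1e-7,
        seed=int(rng.integers(2**31)),
    )
    hap, truth = synthetic_data.simulate_population(cfg)
    swept_te_id = freq_table.index[freq_table["archetype"] == "high"][0]
    swept_te = next(t for t in tes if t.te_id == swept_te_id)
    # relocate the swept TE so its midpoint sits at the planted sweep locus
    tes = [t for t in tes if t.te_id != swept_te_id]
    swept_te = te_frequency.TEInsertion(
        te_id=swept_te_id, family=swept_te.family, order=swept_te.order, chrom="2L",
        start=truth.sweep_position - 100, end=truth.sweep_position + 100,
        canonical_length=swept_te.canonical_length,
    )
    tes.append(swept_te)
    annotations.write_te_bed(sorted(tes, key=lambda t: t.start), out / "inputs" / "tes.bed")
    synthetic_data.write_vcf(hap, out / "inputs" / "sweep_panel.vcf")
    strains = [f"strain{k:03d}" for k in range(cfg.n_haplotypes // 2)]
    state_rows = []
    for k, strain in enumerate(strains):
        a, b = hap.alleles[2 * k, truth.sweep_site], hap.alleles[2 * k + 1, truth.sweep_site]
        call = {0: "absent", 1: "polymorphic", 2: "present"}[int(a == 1) + int(b == 1)]
        state_rows.append({"te_id": swept_te_id, "strain": strain, "call": call})
    pd.DataFrame(state_rows).to_csv(out / "inputs" / "sweep_states.tsv", sep="\t", index=False)

    # FST pairs with two-population neutral null panels
    pair_rows = []
    for pair, (a, b) in {"EU": ("EU1", "EU2"), "NA": ("NA1", "NA2")}.items():
        null_cfg = synthetic_data.SimConfig(
            n_haplotypes=160, n_sites=250, sequence_length=30_000, n_populations=2,
            neutral_fraction=0.9, burnin_generations=60, split_generations=60,
            mutation_rate=2e-7, seed=int(rng.integers(2**31)),
        )
        null_hap, _ = synthetic_data.simulate_population(null_cfg)
        null_path = out / "inputs" / f"fst_null_{pair}.vcf"
        synthetic_data.write_vcf(null_hap, null_path)
        side = {s: sample_meta.set_index("sample_id").loc[s, "latitude_class"] for s in (a, b)}
        pair_rows.append({"pair": pair, "sample_a": a, "sample_b": b,
                          "side_a": side[a], "side_b": side[b], "null_vcf": str(null_path)})
    pd.DataFrame(pair_rows).to_csv(out / "inputs" / "fst_pairs.tsv", sep="\t", index=False)

    # annotations, trees, expression with planted cis effects
    dgrp_strains = [f"dgrp{k:03d}" for k in range(60)]
    emitted = synthetic_data.emit_annotations_trees_expression(
        tes, rng, strains=dgrp_strains, n_eqtl=6, eqtl_beta=1.0,
        te_true_freq={t: float(np.nanmean(freq_table.loc[t, samples].to_numpy(float)))
                      for t in freq_table.index},
    )
    synthetic_data.write_gff3(emitted["genes"], out / "inputs" / "genes.gff3")
    pd.DataFrame(
        [{"family": fam, "newick": nwk} for fam, nwk in emitted["trees"].items()]
    ).to_csv(out / "inputs" / "trees.tsv", sep="\t", index=False)
    emitted["genotypes"].to_csv(out / "inputs" / "eqtl_genotypes.tsv", sep="\t")
    emitted["expression"]["female"].to_csv(out / "inputs" / "expr_female.tsv", sep="\t")
    emitted["expression"]["male"].to_csv(out / "inputs" / "expr_male.tsv", sep="\t")
    pd.DataFrame(
        [{"trait": "stress_response", "gene_id": g.gene_id}
         for g in rng.choice(emitted["genes"], size=len(emitted["genes"]) // 3, replace=False)]
    ).to_csv(out / "inputs" / "candidate_genes.tsv", sep="\t", index=False)
    truth.planted_eqtl = emitted["planted"]
    truth.to_json(out / "inputs" / "truth.json")

    config = RunConfig(
        output_dir=str(out), seed=seed,
        min_samples=4,  # the demo has six samples, not a 91-sample panel
        calls_tsv=str(out / "inputs" / "calls_individual.tsv"),
        pooled_tsv=str(out / "inputs" / "counts_pooled.tsv"),
        samples_tsv=str(out / "inputs" / "samples.tsv"),
        te_bed=str(out / "inputs" / "tes.bed"),
        recombination_tsv=str(out / "inputs" / "recmap.tsv"),
        trees_tsv=str(out / "inputs" / "trees.tsv"),
        sweep_vcf=str(out / "inputs" / "sweep_panel.vcf"),
        sweep_states_tsv=str(out / "inputs" / "sweep_states.tsv"),
        fst_pairs_tsv=str(out / "inputs" / "fst_pairs.tsv"),
        gff=str(out / "inputs" / "genes.gff3"),
        expr_female_tsv=str(out / "inputs" / "expr_female.tsv"),
        expr_male_tsv=str(out / "inputs" / "expr_male.tsv"),
        eqtl_genotypes_tsv=str(out / "inputs" / "eqtl_genotypes.tsv"),
        candidate_genes_tsv=str(out / "inputs" / "candidate_genes.tsv"),
        african_sample="AF",
    )
    report = run_all(config)
    report["truth"] = {"swept_te": swept_te_id, "sweep_position": truth.sweep_position,
                       "planted_eqtl": truth.planted_eqtl}
    return report
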