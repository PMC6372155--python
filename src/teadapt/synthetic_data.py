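"""Synthetic population-genomic data with known ground truth.

Everything the pipeline consumes can be generated here: phased haplotypes
evolved under a forward Wright-Fisher model (neutral, hard sweep, or soft
sweep around a focal biallelic TE marker), per-strain TE calls and pooled
read counts sampled from known true frequencies, gene annotations placed at
controlled distances from TEs, family trees with a planted young/old
terminal-branch mixture, and expression matrices with planted cis effects.
A :class:`SimTruth` record keeps the ground truth for recovery tests.

The simulator is deliberately forward-in-time: selection coefficients and
multiple sweep origins are then exact model inputs rather than coalescent
approximations.  Standing variation is initialized from the neutral site
frequency spectrum (P(count = k) proportional to 1/k) at linkage
equilibrium, and a burn-in builds local LD before any sweep starts.  Scale
is a desk-sized caricature of a Drosophila chromosome arm: a 50-kb region
with a compressed recombination map, chosen so that linkage disequilibrium
decays within a few kb as it does over a few hundred kb in the real genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel, Transcript
from .sweep_scan import HaplotypeMatrix
from .te_frequency import TEInsertion

YOUNG_AGE_CUT = 0.01


class SweepNotEstablishedError(RuntimeError):
    """The focal allele was repeatedly lost before reaching the target frequency."""


@dataclass
class SimConfig:
    """Parameters of one forward simulation run.

    Rates are per bp per generation; ``selection_coefficient`` is the
    multiplicative fitness advantage of a focal-allele copy.  ``sweep_kind``
    is ``"none"``, ``"hard"`` (single origin) or ``"soft"`` (``n_origins``
    independent origins on distinct backgrounds).
    """

    n_haplotypes: int = 200
    n_sites: int = 400
    sequence_length: int = 50_000
    recombination_rate: float = 1e-6
    mutation_rate: float = 1e-8
    selection_coefficient: float = 0.0
    sweep_kind: str = "none"
    focal_position: int = 25_000
    target_frequency: float = 0.6
    init_focal_frequency: float = 0.5
    n_generations: int = 2_000
    burnin_generations: int = 150
    n_origins: int = 3
    neutral_fraction: float = 0.4
    n_populations: int = 1
    migration_rate: float = 0.01
    split_generations: int = 200
    max_restarts: int = 200
    seed: int = 0
    chrom: str = "2L"

    def __post_init__(self) -> None:
        if min(self.recombination_rate, self.mutation_rate, self.migration_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.selection_coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0 <= self.focal_position < self.sequence_length:
            raise ValueError("focal_position outside [0, sequence_length)")
        if self.sweep_kind not in ("none", "hard", "soft"):
            raise ValueError(f"unknown sweep_kind {self.sweep_kind!r}")
        if self.n_populations not in (1, 2):
            raise ValueError("only 1 or 2 populations supported")


@dataclass
class SimTruth:
    """Ground truth of a synthetic dataset."""

    sweep_site: int = -1
    sweep_position: int = -1
    sweep_kind: str = "none"
    s: float = 0.0
    n_origins: int = 0
    true_te_frequencies: dict = field(default_factory=dict)
    planted_eqtl: list = field(default_factory=list)
    neutral_site_ids: list = field(default_factory=list)
    populations: list = field(default_factory=list)
    generations_run: int = 0
    restarts: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# forward Wright-Fisher engine
# ---------------------------------------------------------------------------

def _init_standing_variation(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sites at linkage equilibrium with counts drawn from the neutral SFS."""
    n, m = cfg.n_haplotypes, cfg.n_sites
    positions = np.sort(rng.choice(cfg.sequence_length, size=m, replace=False))
    k = np.arange(1, n)
    sfs = (1.0 / k) / np.sum(1.0 / k)
    counts = rng.choice(k, size=m, p=sfs)
    alleles = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        alleles[rng.choice(n, size=counts[j], replace=False), j] = 1
    return alleles, positions


def _generation(
    alleles: np.ndarray, positions: np.ndarray, cfg: SimConfig,
    fitness: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation: weighted parents, crossover, mutation."""
    n, m = alleles.shape
    p = fitness / fitness.sum()
    par1 = rng.choice(n, size=n, p=p)
    children = alleles[par1].copy()
    n_x = rng.poisson(cfg.recombination_rate * cfg.sequence_length, size=n)
    recombinants = np.flatnonzero(n_x > 0)
    if recombinants.size:
        par2 = rng.choice(n, size=recombinants.size, p=p)
        for k, child in enumerate(recombinants):
            breaks = np.sort(rng.integers(0, cfg.sequence_length, size=n_x[child]))
            odd = np.searchsorted(breaks, positions, side="right") % 2 == 1
            children[child, odd] = alleles[par2[k], odd]
    n_mut = rng.poisson(cfg.mutation_rate * cfg.sequence_length * n)
    if n_mut:
        hi = rng.integers(0, n, size=n_mut)
        si = rng.integers(0, m, size=n_mut)
        children[hi, si] = 1 - children[hi, si]
    return children


def _evolve(
    alleles: np.ndarray, positions: np.ndarray, cfg: SimConfig, rng: np.random.Generator,
    focal: int | None, s: float, generations: int, stop_at: float | None = None,
    demes: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Run up to ``generations`` WF generations; optional focal selection.

    With ``stop_at`` set, stops as soon as the focal-allele frequency reaches
    it; returns (alleles, generations run, focal still segregating or fixed).
    With ``demes`` given, each deme reproduces separately and a symmetric
    fraction ``cfg.migration_rate`` of haplotypes is exchanged per
    generation.
    """
    for g in range(generations):
        if focal is not None and s > 0:
            fitness = np.where(alleles[:, focal] == 1, 1.0 + s, 1.0)
        else:
            fitness = np.ones(alleles.shape[0])
        if demes is None:
            alleles = _generation(alleles, positions, cfg, fitness, rng)
        else:
            new = alleles.copy()
            for d in np.unique(demes):
                sel = demes == d
                new[sel] = _generation(alleles[sel], positions, cfg, fitness[sel], rng)
            alleles = new
            n_mig = rng.poisson(cfg.migration_rate * (demes == 0).sum())
            if n_mig:
                src = rng.choice(np.flatnonzero(demes == 0), size=min(n_mig, (demes == 0).sum()), replace=False)
                dst = rng.choice(np.flatnonzero(demes == 1), size=src.size, replace=False)
                alleles[np.concatenate([src, dst])] = alleles[np.concatenate([dst, src])]
        if focal is not None and stop_at is not None:
            freq = alleles[:, focal].mean()
            if freq == 0.0:
                return alleles, g + 1, False
            if freq >= stop_at:
                return alleles, g + 1, True
    alive = True
    if focal is not None:
        alive = alleles[:, focal].mean() > 0
    return alleles, generations, alive


def simulate_population(config: SimConfig) -> tuple[HaplotypeMatrix, SimTruth]:
    """Forward-simulate phased haplotypes around a focal TE marker.

    Returns the final haplotype matrix (ancestral = 0 coding) and the ground
    truth.  Under ``sweep_kind="hard"``/``"soft"`` the focal allele starts on
    one / ``n_origins`` random backgrounds after the burn-in and is pushed by
    multiplicative selection until ``target_frequency``; runs where it is
    lost are restarted from the pre-origin state, up to ``max_restarts``
    times before :class:`SweepNotEstablishedError` is raised.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    alleles, positions = _init_standing_variation(cfg, rng)
    focal = int(np.argmin(np.abs(positions - cfg.focal_position)))
    s = cfg.selection_coefficient

    # the focal column is controlled explicitly, not part of standing variation
    n = cfg.n_haplotypes
    alleles[:, focal] = 0
    if cfg.sweep_kind == "none":
        k0 = int(round(cfg.init_focal_frequency * n))
        k0 = min(max(k0, 0), n)
        alleles[rng.choice(n, size=k0, replace=False), focal] = 1

    alleles, _, _ = _evolve(alleles, positions, cfg, rng, focal, s if cfg.sweep_kind == "none" else 0.0,
                            cfg.burnin_generations)

    restarts = 0
    gens = cfg.burnin_generations
    if cfg.sweep_kind in ("hard", "soft"):
        k_origin = 1 if cfg.sweep_kind == "hard" else max(2, cfg.n_origins)
        base = alleles.copy()
        while True:
            alleles = base.copy()
            alleles[:, focal] = 0
            alleles[rng.choice(n, size=k_origin, replace=False), focal] = 1
            alleles, g, alive = _evolve(
                alleles, positions, cfg, rng, focal, s,
                cfg.n_generations - cfg.burnin_generations, stop_at=cfg.target_frequency,
            )
            if alive and alleles[:, focal].mean() >= min(cfg.target_frequency, 1.0):
                gens += g
                break
            restarts += 1
            if restarts > cfg.max_restarts:
                raise SweepNotEstablishedError(
                    f"sweep not established after {cfg.max_restarts} restarts"
                )

    demes = np.zeros(n, dtype=int)
    if cfg.n_populations == 2:
        demes[n // 2:] = 1  # deme 0 = source ("Africa")
        alleles, g, _ = _evolve(alleles, positions, cfg, rng, focal, 0.0,
                                cfg.split_generations, demes=demes)
        gens += g

    neutral = np.zeros(cfg.n_sites, dtype=bool)
    candidates = np.setdiff1d(np.arange(cfg.n_sites), [focal])
    n_neutral = int(round(cfg.neutral_fraction * cfg.n_sites))
    neutral[rng.choice(candidates, size=min(n_neutral, candidates.size), replace=False)] = True

    hap = HaplotypeMatrix(
        alleles=alleles, positions=positions, chrom=cfg.chrom, neutral=neutral,
    )
    sample_names = [f"pop{d}" for d in range(cfg.n_populations)]
    freqs = {
        name: float(alleles[demes == d, focal].mean()) for d, name in enumerate(sample_names)
    }
    truth = SimTruth(
        sweep_site=focal,
        sweep_position=int(positions[focal]),
        sweep_kind=cfg.sweep_kind,
        s=s,
        n_origins=0 if cfg.sweep_kind == "none" else (1 if cfg.sweep_kind == "hard" else max(2, cfg.n_origins)),
        true_te_frequencies={"focal_te": freqs},
        neutral_site_ids=np.flatnonzero(neutral).tolist(),
        populations=demes.tolist(),
        generations_run=gens,
        restarts=restarts,
    )
    return hap, truth


# ---------------------------------------------------------------------------
# TE panels and observation emitters
# ---------------------------------------------------------------------------

_FAMILIES = (
    ("jockey", "nonLTR", 5_019), ("F", "nonLTR", 4_708), ("BS", "nonLTR", 5_142),
    ("297", "LTR", 6_995), ("opus", "LTR", 7_521), ("roo", "LTR", 9_092),
    ("pogo", "DNA", 2_121), ("transib2", "DNA", 3_030),
)


def simulate_te_panel(
    n_tes: int, samples: Sequence[str], rng: np.random.Generator,
    chrom: str = "2L", chrom_length: int = 20_000_000,
    class_weights: Mapping[str, float] | None = None,
    african_sample: str | None = None,
) -> tuple[list[TEInsertion], pd.DataFrame]:
    """A panel of TEs with true per-sample frequencies of known archetype.

    Archetypes: ``fixed`` (~0.97-1.0 everywhere), ``high`` (intermediate in
    three or more samples), ``low`` (<= 0.10 everywhere), ``rare`` (near 0).
    Weights default to roughly the proportions seen in natural populations.
    Returns the TE records and a TE x sample true-frequency frame with the
    archetype in an ``archetype`` column.
    """
    weights = dict(class_weights or {"fixed": 0.4, "high": 0.25, "low": 0.25, "rare": 0.1})
    kinds = rng.choice(list(weights), size=n_tes, p=np.array(list(weights.values())) / sum(weights.values()))
    starts = np.sort(rng.choice(chrom_length - 20_000, size=n_tes, replace=False))
    tes, rows = [], []
    for i, (kind, start) in enumerate(zip(kinds, starts)):
        family, order, canonical = _FAMILIES[rng.integers(len(_FAMILIES))]
        length = int(canonical * rng.uniform(0.1, 1.1))
        te = TEInsertion(
            te_id=f"TE{i:04d}", family=family, order=order, chrom=chrom,
            start=int(start), end=int(start) + max(length, 120), canonical_length=canonical,
        )
        tes.append(te)
        if kind == "fixed":
            f = rng.uniform(0.96, 1.0, size=len(samples))
        elif kind == "high":
            f = np.clip(rng.uniform(0.15, 0.9) + rng.normal(0, 0.08, size=len(samples)), 0.0, 0.94)
        elif kind == "low":
            f = rng.uniform(0.0, 0.10, size=len(samples))
        else:
            f = np.where(rng.random(len(samples)) < 0.1, rng.uniform(0, 0.05), 0.0)
        rows.append(dict(zip(samples, f)) | {"te_id": te.te_id, "archetype": kind})
    table = pd.DataFrame(rows).set_index("te_id")
    return tes, table


def _as_freq_frame(truth_or_freqs) -> pd.DataFrame:
    if isinstance(truth_or_freqs, SimTruth):
        return pd.DataFrame(truth_or_freqs.true_te_frequencies).T
    frame = pd.DataFrame(truth_or_freqs)
    return frame.drop(columns=[c for c in ("archetype",) if c in frame.columns])


def emit_te_observations(
    truth, mode: str, coverage: float = 60.0, n_strains: int = 20,
    no_data_rate: float = 0.0, polymorphic: bool = True,
    rng: np.random.Generator | None = None, seed: int | None = None,
) -> pd.DataFrame:
    """Sample raw TE observations from true frequencies.

    ``individual`` mode draws per-strain diploid calls — a strain carries
    Binomial(2, f) insertion copies, reported as absent / polymorphic /
    present, with a configurable no-data rate.  ``pooled`` mode draws a read
    total ~ Poisson(coverage) and presence reads ~ Binomial(total, f).
    ``truth`` is a :class:`SimTruth` or any TE x sample frame of true
    frequencies.  Returns the long-format raw table the frequency module
    consumes.
    """
    if mode not in ("individual", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pooled" and coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    freqs = _as_freq_frame(truth)
    rows = []
    for te_id, per_sample in freqs.iterrows():
        for sample, f in per_sample.items():
            if mode == "pooled":
                total = int(rng.poisson(coverage))
                pres = int(rng.binomial(total, f)) if total else 0
                rows.append({"te_id": te_id, "sample": sample,
                             "presence_reads": pres, "absence_reads": total - pres})
            else:
                copies = rng.binomial(2, f, size=n_strains) if polymorphic else 2 * rng.binomial(1, f, size=n_strains)
                nodata = rng.random(n_strains) < no_data_rate
                for k in range(n_strains):
                    if nodata[k]:
                        call = "no_data"
                    else:
                        call = {0: "absent", 1: "polymorphic", 2: "present"}[int(copies[k])]
                    rows.append({"te_id": te_id, "sample": sample,
                                 "strain": f"{sample}_s{k:03d}", "call": call})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotations, trees, expression
# ---------------------------------------------------------------------------

def emit_annotations_trees_expression(
    tes: Sequence[TEInsertion],
    rng: np.random.Generator,
    strains: Sequence[str] = (),
    gene_distance_bp: tuple[int, int] = (100, 2_000),
    young_weight: float = 0.3,
    n_eqtl: int = 0,
    eqtl_beta: float = 1.0,
    noise_sd: float = 0.5,
    te_true_freq: Mapping[str, float] | None = None,
) -> dict:
    """Gene models, family trees, and (optionally) expression with cis effects.

    One gene is placed next to each TE at a uniform distance within
    ``gene_distance_bp``; terminal branch lengths come from a two-component
    mixture (young < 0.01 with probability ``young_weight``); when ``strains``
    and ``n_eqtl`` are given, per-strain genotypes are drawn from the true
    frequencies and expression = baseline + beta x genotype + Gaussian noise
    for the planted pairs (beta = 0 otherwise).  Returns a dict with keys
    ``genes``, ``trees`` (family -> newick), ``ages`` (te -> branch length),
    ``genotypes``, ``expression`` ({sex -> gene x strain}), ``planted``.
    """
    freqs = dict(te_true_freq or {})
    for te in tes:
        freqs.setdefault(te.te_id, float(rng.uniform(0.05, 0.95)))
    # plant cis effects only where they are detectable: a polymorphic TE
    # genotype and a gene within the 1-kb cis window
    testable = [i for i, te in enumerate(tes) if 0.1 < freqs[te.te_id] < 0.9]
    planted_idx = rng.choice(testable, size=min(n_eqtl, len(testable)), replace=False)

    genes: list[GeneModel] = []
    for i, te in enumerate(tes):
        if i in planted_idx:
            d = int(rng.integers(100, 900))
        else:
            d = int(rng.integers(*gene_distance_bp))
        start = te.end + d
        end = start + 3_000
        tx = Transcript(
            tx_id=f"G{i:04d}.t1", strand="+",
            exons=[(start, start + 500), (start + 1_500, end)],
            cds=[(start + 200, start + 500), (start + 1_500, end - 300)],
            utrs=[(start, start + 200), (end - 300, end)],
        )
        genes.append(GeneModel(
            gene_id=f"G{i:04d}", chrom=te.chrom, start=start, end=end, strand="+",
            transcripts=[tx],
        ))

    by_family: dict[str, list[TEInsertion]] = {}
    for te in tes:
        by_family.setdefault(te.family, []).append(te)
    trees: dict[str, str] = {}
    ages: dict[str, float] = {}
    for family, members in by_family.items():
        names = [te.te_id for te in members]
        pad = max(0, 3 - len(names))
        names += [f"{family}_extra{k}" for k in range(pad)]
        lengths = []
        for name in names:
            if rng.random() < young_weight:
                tbl = rng.uniform(0.0002, YOUNG_AGE_CUT * 0.98)
            else:
                tbl = rng.uniform(YOUNG_AGE_CUT, 0.08)
            lengths.append(tbl)
            ages[name] = tbl
        trees[family] = _caterpillar_newick(names, lengths)

    out = {"genes": genes, "trees": trees, "ages": ages,
           "genotypes": None, "expression": None, "planted": []}
    if strains:
        geno = pd.DataFrame(
            {s: [float(rng.binomial(2, freqs[te.te_id])) for te in tes] for s in strains},
            index=[te.te_id for te in tes],
        )
        planted = []
        betas = pd.Series(0.0, index=geno.index)
        for i in planted_idx:
            betas.iloc[int(i)] = eqtl_beta
            planted.append((tes[int(i)].te_id, genes[int(i)].gene_id, float(eqtl_beta)))
        expression = {}
        for sex in ("female", "male"):
            baseline = rng.normal(5.0, 1.0, size=len(genes))
            expr = np.outer(np.ones(len(genes)), np.zeros(len(strains)))
            expr = baseline[:, None] + betas.to_numpy()[:, None] * geno.to_numpy()
            expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
            expression[sex] = pd.DataFrame(expr, index=[g.gene_id for g in genes], columns=list(strains))
        out["genotypes"] = geno
        out["expression"] = expression
        out["planted"] = planted
    return out


def _caterpillar_newick(names: Sequence[str], lengths: Sequence[float], internal: float = 0.01) -> str:
    """Newick string with the given pendant lengths, balanced topology.

    (A balanced shape keeps the nesting depth logarithmic, so arbitrarily
    large families stay parseable.)
    """
    nodes = [f"{name}:{tbl:.6f}" for name, tbl in zip(names, lengths)]
    while len(nodes) > 1:
        merged = []
        for i in range(0, len(nodes) - 1, 2):
            merged.append(f"({nodes[i]},{nodes[i + 1]}):{internal:.6f}")
        if len(nodes) % 2:
            merged.append(nodes[-1])
        nodes = merged
    return nodes[0].rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# file emitters
# ---------------------------------------------------------------------------

def write_vcf(hap: HaplotypeMatrix, path, sample_prefix: str = "strain") -> None:
    """Write a phased VCF 4.2, two haplotypes per diploid sample column."""
    n = hap.n_haplotypes
    if n % 2:
        raise ValueError("need an even number of haplotypes for diploid VCF output")
    samples = [f"{sample_prefix}{k:03d}" for k in range(n // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hap.chrom},length={int(hap.positions.max()) + 1}>\n")
        fh.write('##INFO=<ID=NEUT,Number=0,Type=Flag,Description="Designated neutral site">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(hap.n_sites):
            info = "NEUT" if hap.neutral[j] else "."
            gts = []
            for k in range(n // 2):
                a, b = hap.alleles[2 * k, j], hap.alleles[2 * k + 1, j]
                gts.append(f"{'.' if a < 0 else int(a)}|{'.' if b < 0 else int(b)}")
            fh.write(
                f"{hap.chrom}\t{int(hap.positions[j]) + 1}\tsite{j}\tA\tT\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{gene.start + 1}\t{gene.end}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for tx in gene.transcripts:
                fh.write(
                    f"{gene.chrom}\tsim\tmRNA\t{tx.span[0] + 1}\t{tx.span[1]}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.tx_id};Parent={gene.gene_id}\n"
                )
                for kind, ivs in (("exon", tx.exons), ("CDS", tx.cds), ("five_prime_UTR", tx.utrs[:1]),
                                  ("three_prime_UTR", tx.utrs[1:])):
                    for s, e in ivs:
                        fh.write(
                            f"{gene.chrom}\tsim\t{kind}\t{s + 1}\t{e}\t.\t{tx.strand}\t.\tParent={tx.tx_id}\n"
                        )


def make_recombination_map(
    chrom: str, chrom_length: int, rng: np.random.Generator,
    n_intervals: int = 20, zero_fraction: float = 0.3,
) -> pd.DataFrame:
    """Two interval recombination-rate estimates with a shared LRR fraction.

    Roughly ``zero_fraction`` of the chromosome gets rate 0 in at least one
    of the two maps (low-recombination regions: centromere- and
    telomere-proximal in the real genome).
    """
    edges = np.linspace(0, chrom_length, n_intervals + 1, dtype=int)
    zero_a = rng.random(n_intervals) < zero_fraction / 2
    zero_b = rng.random(n_intervals) < zero_fraction / 2
    both = rng.random(n_intervals) < zero_fraction / 2
    rate_a = np.where(zero_a | both, 0.0, rng.uniform(0.5, 4.0, n_intervals))
    rate_b = np.where(zero_b | both, 0.0, rng.uniform(0.5, 4.0, n_intervals))
    return pd.DataFrame({
        "chrom": chrom, "start": edges[:-1], "end": edges[1:],
        "rate_a": rate_a, "rate_b": rate_b,
    })
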