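# teadapt

Screening population genomic data for putatively adaptive transposable
element (TE) insertions, in the style of the *Drosophila melanogaster*
reference-TE screens: estimate each insertion's population frequency across
many samples, keep the high-frequency insertions sitting in
high-recombination regions (where selection, not drift, most plausibly drove
them up), and then ask whether independent lines of evidence — haplotype
sweep signatures, population differentiation, negative Tajima's D, age and
length, expression effects — converge on the same insertions.

The package is aimed at population geneticists who have per-strain TE
presence/absence calls (or pooled read counts), phased SNP haplotypes, and
standard annotations, and want a tested, reproducible implementation of the
whole chain, plus a synthetic-data generator with known ground truth to
validate every step.

## What it computes

* **TE frequencies** from per-strain calls, `f = (n_present + ½·n_polymorphic) / n_informative`
  (at least 9 informative strains), or from pooled read support,
  `f = presence_reads / total` with 3 ≤ total ≤ 90; TEs typed in fewer than
  10 samples are dropped, and strains carrying an inversion within 500 kb of
  the TE can be excluded first.
* **Classification**: high/low-recombination region (both of two independent
  map estimates > 0), frequency class (Fixed > 95% everywhere; LowFreq ≤ 10%
  everywhere; HighFreq = not fixed and > 10% in ≥ 3 samples), African /
  out-of-Africa geography for HighFreq TEs, and genomic location
  (exon/UTR/first-intron/other-intron/intergenic at 1 kb).
* **Sweep statistics** at TE markers embedded in phased haplotypes
  (presence = derived allele at the TE midpoint):
  iHS = ln(iHH_A/iHH_D) with trapezoidal EHH integration and 20-bin
  frequency standardization; nSL with pair-shared haplotype lengths counted
  in segregating sites and 10-bin standardization; H1/H2/H12 in 100-SNP
  windows (H12 = Σp²ᵢ + 2p₁p₂). Significance is empirical: two-sided 5% of a
  neutral-SNP null for iHS/nSL, top 15% plus a ≥ 50% TE-membership rule for
  H12, with nulls stratified by ancestral-population frequency.
* **Frequency-based tests**: Weir–Cockerham (1984) pairwise F_ST in its
  haploid variance-components form with stratified 95th-percentile neutral
  nulls and a latitude-concordance filter; Tajima's D in non-overlapping
  500-bp windows with fixed-TE flagging at D < −1.65 (autosomes) / −1.82 (X).
* **cis-eQTL**: OLS of expression on 0/1/2 TE genotype for genes within 1 kb
  of either TE junction, per sex, with Benjamini–Hochberg FDR, and the
  frequency-class contingency summary.
* **Enrichment**: chi-square composition tests (location, order, family;
  Bonferroni across families) and hypergeometric candidate-gene overlap.
* **Synthetic data**: a forward Wright–Fisher simulator (hard/soft sweeps
  around a focal TE, designated neutral sites, two-population splits),
  TE-call and pooled-read emitters, gene/tree/expression emitters with
  planted effects, and ground-truth records for recovery tests.

## Worked example

The single-command demo generates a synthetic workspace — six population
samples, an 80-TE panel, a phased 120-haplotype panel with a hard sweep
(s = 0.1) planted at one HighFreq TE, two F_ST population pairs, and
expression with six planted cis effects — and runs the full pipeline:

```bash
teadapt demo --out-dir demo_run --seed 0
```

prints (abridged):

```
{
 "counts": {
  "tes_input": 80,
  "tes_after_sparse_filter": 80,
  "region": {"HRR": 46, "LRR": 34},
  "freq_class": {"HighFreq": 34, "Fixed": 18, "LowFreq": 18, "Unclassified": 10},
  "young_and_long": 3,
  "tes_sweep_scanned": 1,
  "fst_concordant": 0,
  "tajima_flagged": 0,
  "candidates": 4,
  "eqtl_significant_tes": 9
 },
 "truth": {"swept_te": "TE0000", ...}
}
```

Reading this: the 80 simulated TEs all survive the sparse-sample filter, 46
fall in high-recombination regions, and 34 are HighFreq. The planted sweep
TE (`TE0000`) is scanned against the haplotype panel and lands in the
candidate table (in this run via significant iHS and nSL values), together
with three Fixed TEs picked up by the young-and-long rule. `demo_run/` contains
every per-stage TSV (`te_frequencies.tsv`, `te_classes.tsv`,
`sweep_results.tsv`, `candidates.tsv`, …), the run log, and the ground-truth
sidecar `inputs/truth.json` to compare against.

Each stage is also available as a library call (`teadapt.ihs`,
`teadapt.wc_fst`, `teadapt.tajima_d`, …) and as a CLI subcommand
(`teadapt simulate|tefreq|classify|agelen|sweep|fst|tajima|eqtl|enrich|run|demo`).

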