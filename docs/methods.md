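# Methods

## The screen

A reference TE insertion is a candidate adaptive variant when it is common,
sits where selection is efficient, and carries independent signatures of
selection. The pipeline encodes that as a fixed stage sequence: frequency
estimation → classification → age/length → sweep and frequency-based tests →
evidence union → eQTL and enrichment. The evidence union declares a
polymorphic candidate when a HighFreq TE has at least one significant test
(iHS, nSL, H12, or concordant F_ST), and a fixed candidate when a Fixed TE
in a high-recombination region is young-and-long (terminal branch < 0.01
substitutions/site and > 50% of the family canonical length) or lies within
500 bp of a 500-bp window with significantly negative Tajima's D.

## Statistical definitions and numerical choices

**EHH / iHS.** EHH(x) for an allele at a core site is Σ_h C(n_h,2)/C(n_0,2)
over distinct extended haplotypes from the core to x. The denominator stays
fixed at the core carrier count; haplotypes hitting missing data during the
extension are dropped from the numerator only, so the curve is non-increasing
by construction. iHH is the trapezoidal integral of EHH over map distance
(base pairs when no genetic map is supplied — a constant rate cancels in the
ratio), continued through the first point below the decay floor (default
0.05); hitting a chromosome end first sets a truncation flag. iHS(unstd) =
ln(iHH_ancestral / iHH_derived), standardized to zero mean and unit SD
within 20 equal-width derived-frequency bins of the neutral null (bins with
< 2 values fall back to the pooled SD).

**nSL.** For each allele class, SL is the mean over carrier pairs of the
number of consecutive sites (the core counts once) over which the pair is
identical, extending left and right until the first mismatch; nSL(unstd) =
ln(SL_A/SL_D), standardized within 10 equal-occupancy frequency bins.
nSL requires a missing-free matrix; strains and then sites carrying missing
data are removed first (`HaplotypeMatrix.drop_missing`).

**H12.** Haplotypes identical over a 100-SNP window centered on the core
(windows shrink, flagged, at chromosome ends; haplotypes with missing data
in the window are dropped) are grouped; with frequencies p₁ ≥ p₂ ≥ …,
H1 = Σp²ᵢ, H12 = H1 + 2p₁p₂, H2 = H1 − p₁².

**Empirical significance.** All sweep thresholds come from the statistic's
distribution at designated neutral SNPs, stratified where ancestral-range
(African) frequencies are available into high (> 0.10) and low strata.
iHS/nSL flag |z| beyond the 95th percentile of the null |z| — "outside the
5% tail" is read two-sided, with a one-sided switch. H12 flags values above
the null's 85th percentile *and* requires that at least one of the three
most frequent window haplotypes is carried by ≥ 50% of its member strains
(the membership rule is read per haplotype group, which is the stricter of
the two possible readings). Nulls built from fewer than 100 values warn.

**F_ST.** The Weir–Cockerham (1984) two-population variance-components
estimator in its haploid form (average heterozygosity set to zero), suitable
for phased haplotypes and inbred strain panels; monomorphic loci are
flagged undefined. Pooled samples enter through pseudo-counts with effective
sample size min(2·n_strains, supporting reads). Significance is the 95th
percentile of the frequency-stratified neutral-SNP null, and candidates must
be significant in ≥ 2 population pairs with the high-frequency side on the
same latitude class every time.

**Tajima's D.** Standard constants (Tajima 1989), π from site allele counts,
computed in non-overlapping 500-bp windows; windows with no segregating
sites give missing D. Default cutoffs −1.65 (autosomes) and −1.82 (X) can be
replaced by the 5% quantile of high-recombination windows per chromosome
type; "near" a fixed TE means within 500 bp (one window), configurable.

**eQTL.** Expression ~ genotype OLS per sex with 0/1/2 additive coding,
pairwise deletion of missing strains, pairs skipped when fewer than three
complete strains remain or the genotype is constant. BH FDR is applied
within each sex; at the reporting level a TE is "significant" on raw
p < 0.05 in at least one sex (the published contingency counts imply raw-p
counting), with the FDR < 0.05 subset reported separately.

**Enrichment.** Per-label 2×2 chi-square without continuity correction
(Bonferroni across family labels); hypergeometric upper tail for
candidate-gene overlap with the full annotated gene set as the default
background (the original background is not recoverable, so it is
configurable). Gene-to-TE assignment: all genes < 1 kb, else the single
closest (ties return both, flagged).

**Classification details.** HighFreq is implemented as "not Fixed" plus the
> 10%-in-≥ 3-samples rule; a strict mode additionally requires < 95% in every
sample (the two published phrasings differ). The African high-frequency
cutoff reuses the 10% threshold, which is not stated for that side.
Polymorphic (heterozygous) strain calls count as 0.5 allele copies — a
documented, configurable choice; the original weighting is unstated.
Location precedence is coding exon > UTR > non-coding exon > intron, with
"first intron" evaluated on the longest annotated transcript; a TE inside a
gene span but outside annotated features counts as other-intron.

## The synthetic-data generator

A forward Wright–Fisher simulator of n haploid genomes: multinomial parent
sampling weighted by 1 + s per focal-allele copy, Poisson(rL) crossovers per
offspring against a second weighted parent, finite-sites mutation flips, and
standing variation initialized at linkage equilibrium with site counts drawn
from the neutral spectrum P(k) ∝ 1/k. Hard sweeps start the focal allele on
one background after the burn-in, soft sweeps on k ≥ 2 backgrounds;
replicates losing the allele restart from the pre-origin state up to a cap.
Two-population scenarios split the population in half after the burn-in and
evolve the demes with symmetric migration, the source deme standing in for
the ancestral (African) range.

Default scale is a desk-sized caricature: 200 haplotypes, 50 kb, 400 sites,
r = 10⁻⁶ per bp per generation — a compressed map chosen so that LD decays
within a few kb the way it decays over a few hundred kb in a real fly
chromosome arm — and a 150-generation burn-in (< N, so standing variation
survives; runs several times N long would lose all variation, which the
two-population emitters avoid by using shorter splits and a visible mutation
supply). "Short-intron-like" neutral sites are a labeled random subset of
sites: the calibration contract needs neutrality and matched frequency, not
literal intron models. The generator does **not** emulate demography,
base-level reads, gene conversion, or linked background selection;
passing recovery tests here shows the statistics and their calibration are
implemented correctly, not that the pipeline's power on real fly data equals
the synthetic power.

Observation emitters: individual strains are diploid, carrying
Binomial(2, f) insertion copies reported as absent/polymorphic/present with
a configurable no-data rate; pooled samples draw Poisson(coverage) reads and
Binomial(total, f) presence reads. Terminal branch lengths come from a
two-component mixture (young uniform on (0.0002, 0.0098), old uniform on
(0.01, 0.08), default young weight 0.3) written into balanced Newick trees.
Planted cis effects go only where they are detectable — a polymorphic TE
genotype and a gene inside the 1-kb cis window — so recovery rates measure
the scan, not the planting geometry.

## Recovery benchmarks

`pipeline.sweep_recovery_rates` measures per-test flag rates at the focal
marker over hard-sweep replicates (s = 0.1, sweeps caught at frequencies
drawn uniformly from 0.4–0.8) against an empirical null from the neutral
SNPs of independent neutral replicates under identical conditions. The
neutral false-positive rate is measured on neutral replicates with a random
segregating site of sweep-like frequency (0.4–0.9) standing in for the TE
marker: a neutral insertion is genealogically exchangeable with any neutral
variant of matched frequency, whereas a column initialized at high frequency
in linkage equilibrium would behave like an infinitely old allele and bias
the rate. Because mid-frequency sites have heavier-tailed standardized
values than the pooled null, per-test false-positive rates run slightly
above the nominal 5%; the benchmark therefore reports power *relative to its
own measured neutral rate* per test.

## Known limitations

* The haploid WC84 form and the pooled pseudo-count rule are documented
  surrogates; the exact allele-count construction used upstream of the
  original screen is not recoverable.
* Sweep power at desk scale is modest (tens of percent per test at s = 0.1);
  the acceptance benchmark asks for separation from the neutral rate, not
  for the original screen's counts, which depended on 91 real samples.
* DAVID-style GO clustering is out of scope; the hypergeometric and
  chi-square primitives it rests on are provided instead.
* The run log records counts at every filter, but stage outputs are plain
  TSVs — no workflow-manager integration.
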