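# Methods

`arctic-sweep` implements four complementary routes to candidate loci in a
focal population that recently colonized a new environment, together with a
synthetic-cohort generator that makes every route testable against known
truth. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Study design assumed by the analyses

All analyses assume three diploid populations with the topology
`((focal, sister), comparison)`: a focal island population (default n = 28
individuals), its closest relative (n = 13), and a more distant mainland
population (n = 12). For the derived-allele and CNV analyses the sister and
comparison populations are pooled into a single "mainland" group (n = 25);
for the deletion analysis the comparison cohort is an 11-genome outgroup
panel. These defaults are the cohort structure the pipeline is designed
around and can be changed freely in configuration.

## Synthetic cohort generator

**Drift model.** Per site, an ancestral derived-allele frequency is drawn
from Beta(0.8, 0.8) (a U-shaped spectrum concentrating mass near fixation
and loss, as site-frequency spectra do, while keeping enough intermediate
polymorphism for window statistics). Each branch of the population tree
then transforms the parental frequency through the Balding–Nichols kernel,
`p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, with branch-specific drift parameters
F (defaults: internal 0.05, focal 0.08, sister 0.05, comparison 0.05 —
chosen to put genome-wide focal-vs-comparison Hudson F_ST near 0.1, the
moderate-differentiation regime between an island subspecies and its
mainland relatives). The kernel satisfies E[F_ST] ≈ F between parent and
child, which makes the generator checkable against closed-form and
Monte-Carlo oracles. Genotypes are binomial draws from the population
frequency; sites monomorphic across the whole sample are dropped, because a
variant caller only emits variant sites. There is no linkage
disequilibrium: sites are independent. A haploid outgroup-species column
carrying the true ancestral allele is emitted for polarization.

**Sweeps.** A sweep locus forces the focal derived-allele frequency to a
target (default 0.95) and both other populations to a low value (0.05)
across a fixed interval — the frequency configuration a completed sweep
leaves behind, without modelling the sweep's haplotype structure.

**Planted coding variants.** Effect-annotated variants are planted at
*exact* allele counts: `round(call_rate · n)` individuals are called and
exactly `round(freq · 2 n_called)` of their chromosomes carry the derived
allele. Exact counts (rather than binomial draws) keep a planted variant on
the intended side of a downstream frequency threshold at any sample size;
at n = 28 a binomial draw targeted at 0.8 falls below the 0.7 retention
threshold about 4% of the time, which would make exactness tests
meaningless. Background effect annotations are restricted to LOW/MODIFIER
classes so that the set of variants that *should* survive the filter is
exactly the planted qualifying set.

**Depth tracks.** Per-genome per-site depths are Poisson with the genome's
nominal coverage (defaults 23× for the 28 focal genomes and 123/11 ≈ 11.2×
for the 11 comparison genomes, so the summed focal and comparison tracks
average ≈644 and ≈123 per site). A fixed deletion zeroes the depth of every
focal genome over its interval. Real depth tracks have GC and mappability
covariance that Poisson noise does not; the mappability mask handles the
dominant term (unique-alignment dropout) explicitly.

**CNV matrix.** Each individual draws two allele classes per locus from its
population's class frequencies over {A: single copy, CN0: deletion, CN2:
duplication, CNH: >2 copies}; diploid copy number is the summed per-allele
copy contribution (A = 1, CN0 = 0, CN2 = 2, CNH = 3, capped at 5). Because
copy numbers above 2 have no unique pair decomposition, the package fixes a
canonical mapping (0→CN0/CN0, 1→CN0/A, 2→A/A, 3→A/CN2, 4→CN2/CN2,
≥5→CN2/CNH), and the generator records its draws through the same mapping
so recovery is exact by construction. Background (non-differentiated) loci
share one frequency vector between populations, with the CNV-allele
frequency drawn per locus from a rare-skewed spectrum (0.5·Beta(0.3, 8),
assigned to CN0 with probability 0.7, else CN2): most segregating
structural variants are rare. This choice matters for the DAPC validation
— see below.

Determinism: every simulator is seeded and produces byte-identical output
for identical seeds; the pipeline derives per-stage seeds from one master
seed by fixed offsets so stages are independently reproducible.

## Variant filters

Genotypes with depth < 5 become missing; heterozygous genotypes whose
reference-allele balance (ref reads / depth) falls outside [0.2, 0.8]
become missing (homozygotes are exempt — balance 0 or 1 is what a correct
homozygote looks like). SNPs within 5 bp of an indel anchor are removed,
as are sites on excluded chromosomes (the X by default; every statistic
here assumes autosomal diploidy). Base quality is assumed applied by the
caller upstream and is recorded for provenance only. The filter is
idempotent and monotone in its thresholds.

## Window scan: Hudson F_ST, PBS, Tajima's D

Per site, the Hudson F_ST estimator with finite-sample correction:
numerator `(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`, denominator
`p1(1−p2) + p2(1−p1)`, with n counted in called chromosomes; sites with
fewer than 2 called chromosomes in either population are skipped. Windows
(default 50 kb, step 10 kb, laid from coordinate 0 per chromosome, last
partial window kept) aggregate by ratio of sums, the standard
small-sample-robust combination. Window F_ST is clamped to [0, 1−1e−9]
before the branch-length transform `T = −log(1−F_ST)`; the focal branch
length is `PBS = (T_fs + T_fc − T_sc)/2`. Negative PBS is reported as
computed — it never reaches the upper outlier tail. Frequencies are
best-guess genotype frequencies; genotype-likelihood uncertainty at low
coverage is not propagated, a documented simplification.

Tajima's D uses π computed from allele counts (`Σ k(n−k)/C(n,2)` with
per-site n) and Watterson's S/a1, with the standard e1/e2 normalization.
Under missingness the normalizing constants use the window-median n (exact
small-sample theory has no single n in that case). Windows with no
segregating site, or n < 3, are undefined rather than NaN — and at n = 3
the variance constants are identically zero, so D is undefined there too.
Windows with fewer than `min_sites` (default 10) sites are excluded from
all percentile computations.

Outliers are windows with PBS at or above the empirical 99.9th percentile
(linear interpolation, pooled genome-wide); ties at the threshold are
included. Because sliding windows overlap, one sweep yields several
outlier windows; gene hits are deduplicated per gene and a merged
outlier-region track is also emitted. The Tajima's D contrast reports the
mean and the proportion of positive values per population for outlier vs
non-outlier windows.

## Derived-allele frequency filter

Sites are polarized against the outgroup-species allele: ancestral = the
outgroup allele when it matches REF or ALT, derived = the other allele;
sites matching neither are excluded. Variants of LOW/MODIFIER effect are
dropped, then a variant is retained iff derived frequency ≥ 0.7 in the
focal population, ≤ 0.25 in the pooled mainland group (both bounds
inclusive), and the call rate is ≥ 0.5 in each population separately. The
asymmetric thresholds leave room for drift after selection and for the
allele to have segregated as standing variation on the mainland.

## CNV DAPC

Variables are per-locus per-allele-class dosages (0/1/2 within the
canonical pair), column-centered without scaling; constant columns are
dropped with a logged count. PCA is computed by SVD and the first 5
components retained; a single linear discriminant between the two groups
is fitted in PC space with the pooled within-group covariance (ridge
fallback only if the pool is exactly singular, as in perfect separation).
The discriminant axis is rotated back to variable space, squared loadings
are normalized to sum to 1, and a locus is an outlier when any of its
allele-class loadings exceeds the threshold (default 0.0005).

**The loading threshold and the noise floor.** A normalized-loading
threshold is an absolute constant, so its meaning depends on the number of
variables. At genome scale (thousands of CNV loci) 0.0005 is an order of
magnitude above the uniform loading 1/p; at 200 loci (~400 variables) the
uniform loading is 0.0025 — five times the threshold — and PCA eigenvector
sampling noise at ~50 individuals spreads a nontrivial share of loading
onto background variables. The validation therefore plants fixed
differences (CN0 frequency 1.0 vs 0.0) on a rare-skewed background, the
regime in which the threshold cleanly separates signal from noise at this
locus count; with a common-polymorphism background (minor class frequency
~0.1 shared across 200 loci) a third of background loci would exceed
0.0005 purely through estimation noise. The pipeline demo, with 120 loci,
accordingly uses a proportionate threshold of 0.01. Practitioners applying
the default threshold should have at least a few thousand loci.

## Large-deletion caller

A mappability mask is built first: every 50-mer of the reference (step
1 bp) is counted over both strands; per-site mappability depth is the
number of covering 50-mers that occur exactly once; sites with depth < 25
are unmappable, and unmappable runs within 250 bp merge. Contigs shorter
than 50 bp are wholly unmappable, and contig edges (≤ ~25 bp) are always
masked by the window arithmetic.

Depths are summed per cohort; masked sites carry no evidence. Candidate
windows (100 bp, non-overlapping — about a fifth of the minimum call
length, giving breakpoint resolution without single-site noise
sensitivity) require focal summed depth exactly zero at every unmasked
site and comparison mean ≥ 50% of the expected comparison sum; windows
with under half their sites unmasked are skipped and do not break a run,
so deletions interrupted by masked sequence merge across it. Adjacent
candidates merge; sub-deletions within 250 bp merge when the intervening
region's focal mean is below 5% of the expected focal sum (tolerating
stray mis-mapped reads inside a true deletion). Calls shorter than 500 bp
are discarded, and the scan is restricted to the configured autosomes.
Merge provenance (which runs joined) is kept on every call.

With 28 focal genomes the summed focal depth has mean ≈644, so a single
site of genuine sequence essentially never shows cohort-wide zero depth
(P ≈ e^−644); the strict-zero rule is therefore not fragile at this
cohort size, and recovery on synthetic tracks is exact (recall and
precision 1.0 for planted deletions ≥600 bp, breakpoints within one
candidate window).

## Pipeline

`run_pipeline` executes simulate → filter → scan → outliers → derived →
cnv → dels from one YAML configuration, writes every intermediate
(VCF/BED/GFF3/TSV/JSON), and emits a combined report: per-approach gene
lists, their union with provenance, and the pairwise overlap matrix
between approaches (reported as a statistic, not asserted). Identical
configurations produce byte-identical artifacts.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that each statistic matches an independent
implementation, and that each discovery route recovers exactly the signals
the generator planted under the stated study conditions. They do not
demonstrate performance on real data: the generator has no linkage
disequilibrium, no GC or mappability covariance in depth, no genotyping
error beyond binomial sampling, and its background models are idealized.
In particular, absolute outlier counts from an empirical percentile
threshold are properties of each dataset's tail, and are not comparable
across datasets or to any fixed expectation.
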