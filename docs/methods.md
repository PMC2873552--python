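# Methods

## Haplotype entropy

Within a window of `w` consecutive SNPs, the chromosomes of one population
are partitioned into haplotype classes by exact string identity over the
window, and the Shannon entropy of the class frequencies is computed in
bits: S = −Σ p·log₂p, with 0·log 0 ≡ 0. Bounds: 0 ≤ S ≤ log₂(n) for n
chromosomes, the extremes attained by a single class and by n singletons.
The statistic is alphabet-agnostic — biallelic 0/1 panels are the normal
case, but any integer coding works in permissive mode, and merging two
haplotype classes can only lower S (coarsening monotonicity; property
tested).

**Window placement.** Scores are per SNP with the window centred on the
focal SNP, (w−1)/2 SNPs on each side; `w` must be odd. A symmetric window
is the only placement that makes a score attributable to its SNP. Edge SNPs
whose centred window does not fit inside their chromosome are marked
invalid, not scored on a truncated window — variable window sizes would
distort the empirical null.

**Filters.** Windows whose physical span (pos of last SNP − pos of first)
exceeds `max_span_bp` (default 200,000 bp, strict inequality) are excluded:
very long windows arise in marker deserts and carry little comparable
haplotype information. SNPs on sex chromosomes are excluded by default; the
label set {X, Y, chrX, chrY} is configurable because naming is
dialect-dependent. Every scan reports how many SNPs each filter removed
(`filter_counts`) — this is the audit trail for the exclusions.

**Defaults.** `w = 21` SNPs. The window-size sweep (`window_sweep`)
reproduces the trade-off that motivates it: very small windows hold little
diversity; very large ones make every haplotype unique, so S saturates at
log₂(n) and differences vanish; the between-population median |ΔS| peaks at
intermediate sizes (tens of SNPs).

**Missing data.** Loaders reject missing allele calls by default; an
opt-in mode drops affected SNPs before scanning. Entropy over partially
observed haplotype strings is undefined, and phased reference panels are
complete in practice.

## The two-population ΔS scan

ΔS = S_pop1 − S_pop2 per SNP, computed only where both populations' windows
are valid; the scan is exactly antisymmetric under swapping the panels.
Significance is empirical against the genome-wide ΔS distribution itself:
for a value at or above the median, p = (# values ≥ it)/M; below the
median, p = (# values ≤ it)/M — a one-sided rank within the observed sign
direction, no multiple-testing correction. This assumes most of the genome
is neutral with respect to differentiating the two populations and requires
no demographic model. Consequences worth knowing:

* the most extreme SNP scores exactly 1/M, so resolution scales with the
  number of valid SNPs (a few hundred thousand SNPs give p ~ 10⁻⁶);
* each tail holds ≈ `tail_fraction`·M SNPs by construction (calibration is
  per tail: the nominal 0.1% tails jointly cover ≈0.2% of SNPs);
* ties at the tail threshold are included (conservative toward more
  candidates).

Tail labels are expressed as "LD specific to the lower-entropy population"
(upper ΔS tail ⇒ pop2-specific LD), avoiding any hard-coded population
naming. Gene mapping assigns a signature SNP to every gene whose
transcribed-region interval contains its position (1-based inclusive; BED
input is converted from 0-based half-open). A gene's p is the minimum p over
its mapped SNPs — a deliberate, documented reduction; with ~1-SNP-deep
signatures the choice rarely matters.

`overlap_test` compares two signature gene lists against a universe of U
genes: expected overlap |A||B|/U, observed |A∩B|, 2×2 chi-square without
continuity correction. With expected counts below 5 the chi-square
approximation is rough; the function warns and offers Fisher's exact test.

`compare_entropy_distributions` is a two-sided Mann–Whitney U on the valid
S values of two tracks (delegated to scipy), reporting which population has
the greater median.

## Integrated EHH comparator

EHH at offset x from a core SNP is the probability that two chromosomes
agreeing at the core are identical over every SNP from the core out to x.
This implementation uses the site-level, pooled-allele form: EHH(x) =
Σ_h C(m_h,2) / Σ_a C(n_a,2), with n_a the core allele counts and m_h the
extended-haplotype counts. Pooling gives one score per SNP (the form used
by cross-population EHH statistics); a per-allele variant would condition
on one core allele and is deliberately not the default. Cores where no two
chromosomes agree (all alleles singletons) are undefined and emitted as
missing, never zero — zeros would fabricate signal at singletons.

I is the trapezoidal integral of EHH over offsets in **SNP-index units**
(step 1, both directions summed), so 0 ≤ I ≤ w−1 and I is comparable
SNP-for-SNP with S regardless of physical marker spacing; for the same
reason the I scan applies no physical-span filter. log(I) (natural log) is
provided for plotting. Cores with minor allele frequency < 0.05 are flagged:
EHH-family scores are known to be unstable there.

## Wright–Fisher gradient simulator

Model chromosomes carry L = 500 loci. The recombination probability
between locus j and j+1 is r_j = exp(−j/25) per transmitted gamete per
generation — interpreted as an interval rate (crossovers happen between
loci; 499 intervals, the last locus's nominal rate unused). The decay
constant 25 spans r ≈ 0.96 at one end to r ≈ 2.1×10⁻⁹ at the other, so a
single chromosome covers free recombination through complete linkage.

Reproduction is neutral Wright–Fisher over N diploids: every offspring
draws two parents uniformly with replacement (selfing allowed — standard
WF); each gamete starts on a random parental chromosome and crosses over
per interval with independent Bernoulli(r_j) draws, so multiple crossovers
per gamete are possible (r_1 ≈ 1 is a probability, not a Poisson
intensity). Mutation is a symmetric 0↔1 flip at rate μ per locus per
generation (default 2×10⁻⁹; a 100-fold-higher 2×10⁻⁷ variant is a config
away), applied after recombination via a sparse binomial draw when μ is
tiny. Initial allele frequencies k are drawn once per locus from
Uniform(0,1) and chromosomes seeded i.i.d. Bernoulli(k) — starting
inter-locus LD is ≈ 0, so all end-state linkage structure is built by drift
against the recombination gradient. Sampling takes whole diploids
(n_sample/2 individuals, both chromosomes), and every run is reproducible
from (seed, config); replicate seeds derive from a SeedSequence.

**Problem sizes.** `SimConfig.full_scale()` exposes the full-scale conditions
(N = 10,000 diploids, 5,000 generations, 100 replicates). The package's
working defaults are the scaled conditions N = 1,000, G = 1,000, 10
replicates — about 20 s per replicate on one core — which preserve the
qualitative regime (G = N = 1,000 keeps G/2N = 0.5, matching the 5,000/20,000
ratio of the full-scale run, so drift has comparable bite). The
simulation-based tests use these scaled conditions; the null-calibration
test uses even shorter runs (N = 300, G = 120) because a random split of one
population is a valid null regardless of how close the population is to
mutation–drift equilibrium.

**Verified dynamics.** Unit tests check the classical drift expectation
(heterozygosity decays by (1−1/2N) per generation), exact copying when
recombination and mutation are off, determinism, and that initial
inter-locus correlations are at the 1/(2N) noise floor.

## What the simulator does and does not emulate

It generates the haplotype-structure gradient the scan is designed to
detect, under pure neutrality with uniform marker spacing and a fixed
mutation model. It does not model demography (growth, bottlenecks,
migration), selection, variable marker density or ascertainment bias, SNP
genotyping or phasing error. Tests passing on these panels show that the
statistics measure LD strength and that the two-population machinery is
calibrated under exchangeability; they do not certify behaviour on real
human panels, where demography and ascertainment shape the ΔS
distribution (which is precisely why significance is empirical rather than
model-based).

## Numerical conventions

* Entropy in bits (log base 2) throughout; 0·log 0 ≡ 0; differences exact
  float subtraction (antisymmetry is exact, not approximate).
* Haplotype grouping is exact integer matching (`np.unique` over columns),
  never hashed strings of floats.
* Empirical p via sorted-array rank lookups (`searchsorted`); degenerate
  all-identical distributions return p = 1 with a warning; fewer than 1,000
  values warn that tail resolution is coarse.
* Bootstrap CIs of medians (window sweep) use 200 resamples and a fixed
  generator seed; results are bit-reproducible given (inputs, seed).
* EHH refinement proceeds outward one SNP at a time by splitting label
  groups, guaranteeing the non-increase of EHH with |offset| structurally.
* TSV output: S and ΔS to 6 decimals, p in scientific notation, invalid
  entries as `NA`.

## Panel dialects

Phased VCF is read through cyvcf2 (GT must use the phased `|` separator;
`/` raises). The legacy HapMap phased text dialect — header
`rsID position_b36 <one column per chromosome>`, one whitespace-separated
row per SNP — is implemented from the public format description. Since the
public files are per-chromosome and carry no chromosome column, the writer
adds a `#chrom=<label>` comment the reader honors. Nucleotide alphabets
(A/C/G/T) are recoded to 0/1 lexicographically per site; an already-numeric
{0,1} alphabet is taken verbatim so simulator panels round-trip bit-exactly
(a lexicographic recode would corrupt monomorphic all-`1` rows). Round-trip
equality on both dialects is property-tested.

## Known limitations and open choices

* The pooled-allele EHH form is one of two defensible readings of a
  site-level I; the per-allele alternative skews harder at low MAF. The
  choice is isolated in `ehh_profile` and documented above.
* Gene-level p = min SNP p ignores gene length; long genes collect more
  SNPs and hence more minima. Signature-oriented use (short tails) keeps
  the bias small.
* Under a neutral two-timepoint drift construction (one lineage sampled
  before and after extra generations), the mean entropy deficit at
  low-recombination loci is positive on average — diversity lost to drift
  is not re-randomized — but per-SNP *extreme* ΔS values tend to land in
  the mid-gradient, where window-to-window ΔS variance peaks, rather than
  at the fully linked end, where ΔS is spatially flat (whole blocks move
  together). Localization claims about signature SNPs on such panels
  should be made at the block level, not the SNP level.
* The empirical-p machinery assumes exchangeability of SNPs under the
  null; strong local autocorrelation of ΔS (adjacent overlapping windows)
  makes signature SNPs arrive in runs, so signature *counts* are not
  independent-SNP counts.
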