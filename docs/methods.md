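# Methods

This note documents the models, estimators, defaults and numerical
choices behind `dmrdose`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Methylation levels

All levels are coverage-weighted: `wml = Σ meth / Σ (meth + unmeth)`
over the cytosine set in question. A set with zero total reads has an
undefined level, carried as NaN and excluded from histograms (their
count is reported separately). The weighted estimator makes pooling
replicates equivalent to concatenating their reads; a mean of per-site
proportions would not have that property and is never used.

Symmetric CG dinucleotides contribute two records (one cytosine per
strand) that are never pooled into a single site. Cytosine reports list
both strands; collapsing them is an opinionated transformation that the
rest of the pipeline does not need, so each strand's record enters the
sums on its own coordinates.

Metagene profiles split a 2 kb upstream flank into `n_flank_bins` equal
bins (default 100, i.e. 20 bp/bin), rescale the body to `n_body_bins`
(default 100) by proportional assignment
`floor(relative_position × n_body_bins)`, and likewise downstream.
Minus-strand features are index-reversed so bin 0 is always 5′;
unstranded repeats are treated as plus-strand. Counts are pooled across
features first and converted to levels at the end, so each bin is a
weighted level of pooled cytosines rather than a mean of per-feature
profiles (the two differ when features have unequal coverage).

## DMR calling

The caller implements the noise-filter strategy between two replicate
groups, per context and chromosome:

1. **Pooling.** Replicate counts are summed per (chrom, position,
   strand). No per-replicate dispersion model is fitted; the test below
   operates on pooled counts, so biological variability between
   replicates is absorbed rather than modelled.
2. **Smoothing.** Methylated and total counts are placed on the dense
   per-bp grid and convolved with a Gaussian kernel truncated at 3σ;
   the smoothed proportion is the ratio of the two convolutions (the
   kernel normalisation cancels). Implementation uses
   `scipy.ndimage.gaussian_filter1d`, verified in tests against a
   direct double-loop kernel sum to 1e-10.
3. **Candidates.** Maximal bp runs where the smoothed difference stays
   at or beyond the context's minimum proportion difference (ties at
   the threshold are included). A run's interval — and hence the span
   the size filter sees — is the extent of the signal on the smoothed
   curve, not the first-to-last-cytosine distance: cytosine spacing is
   irregular, and measuring spans between sparse sites systematically
   under-measures CG regions (a 100 bp region with ~6 CG dinucleotides
   often spans < 50 bp site-to-site). Runs without at least one covered
   cytosine in each group are dropped.
4. **Testing.** Two-sided Fisher's exact test on the pooled 2×2 table
   `[[meth_cmp, unmeth_cmp], [meth_ref, unmeth_ref]]` per candidate
   (p = 1 for an all-zero table by convention), then Benjamini–Hochberg
   across all candidates of one context and comparison.
5. **Filters.** Keep q < 0.05, span ≥ min size (50/50/25 bp for
   CG/CHG/CHH), |pooled proportion difference| ≥ 0.40/0.30/0.10
   (inclusive), mean coverage ≥ 8 reads per cytosine, and
   ≥ `min_cytosines` (default 4) covered cytosines. Mean coverage is
   `(total reads of both groups) / (n_cytosines × 2)` — the bound is
   read as symmetric in the groups rather than per-group.
6. **Merging.** Same-context, same-direction neighbours with a gap
   < 200 bp are fused; pooled counts are re-summed, the Fisher test is
   recomputed on the merged table, and q-values re-adjusted across the
   merged set. Merging never takes a min/max of the component p-values,
   so reported statistics always describe the reported interval.

Direction is `hyper` when the comparison group is more methylated than
the reference over the region. The whole chain is antisymmetric:
swapping group roles yields identical intervals with directions
flipped — an exact property, enforced by test.

### Kernel bandwidth

`kernel_window_bp` (default 50) is the full kernel window; the Gaussian
σ is window/6, so the 3σ truncation coincides with the half-window
(25 bp). The half-support is deliberately matched to the smallest
minimum DMR span (25 bp, the CHH class): a kernel that is much wider
than the feature borrows mass from the unchanged flanks and dilutes a
minimum-size CHH region at its detection threshold (0.10) to roughly
0.10 × (kernel mass inside the region) < 0.10, making the smallest DMR
class undetectable by construction. Kernel-mass arithmetic, not tuning,
sets this default; it is configurable (`--bandwidth` on the CLI).

### What the caller does not do

No beta-binomial or other dispersion modelling; no per-cytosine testing
modes; no bin-based calling. Fisher-on-pooled-counts treats replicates
as exchangeable libraries — with few replicates and planted effects this
is appropriate, but on real data with strong replicate heterogeneity it
is anti-conservative.

## DMR–gene association

Gene windows are upstream flank `[start−2000, start)`, body
`[start, end)` and downstream flank `[end, end+2000)` in 0-based
half-open coordinates, exchanged for minus-strand genes and clipped at
zero. A link is any (DMR, gene, window) pair with ≥ 1 bp overlap; a DMR
straddling a boundary links to both windows, and counting is per link
(region panels count a straddling DMR once per window). The multi-DMR
taxonomy instead deduplicates by DMR — a DMR in two windows of one gene
is one DMR — and classifies DEG genes as single, unidirectional-multi
(all linked DMRs share direction) or bidirectional-multi. Both
link-level counts and gene-level classes are emitted, since either
deduplication convention is defensible for region panels.

DEG status uses strict thresholds (FDR < 0.05 and |log₂FC| > 1), so
rows exactly at a boundary are not significant. Non-significant genes
are excluded from DMR-DEG counts but retained in links, which the
dosage summary's "all DMR-associated genes" panel consumes.

## Allele dosage

Tetraploid genotypes (e.g. `0/0/1/1`) give a per-sample dosage 0–4 = the
count of alternative-allele indices. Missing genotypes are carried as
missing and excluded from sums, never imputed as zero. Filters:
biallelic single-base SNPs; QUAL ≥ 30; per-sample depth in [10, 50]
(both bounds inclusive — "between" read strictly would be an
undocumented exclusion of the printed endpoints); minor allele
frequency from dosages, `freq = Σ dosage / (4 × n_genotyped)`, with both
`freq > 0.1` and `1 − freq > 0.1` required. Dosage-based frequency is
the only frequency available after variant calling, which fixes the
denominator choice.

Per DMR, dosages are summed over SNPs inside the DMR interval itself
(not the enclosing gene window), per cultivar; the relation is the sign
of (comparison − reference). DMRs with no usable SNP are kept as
"equal" (0 = 0) and flagged via `n_snps = 0` so sensitivity analyses
can drop them. The deamination subset keeps (ref, alt) in
{C:T, T:C, G:A, A:G} — the transitions attributable to deamination of
(methyl)cytosine on either strand, including the cases where the
reference genome carries the derived allele.

## Synthetic data

The generator emulates the study's data shapes, not its genome:

* Random-composition chromosomes (default 2 × 500 kb); genes packed
  without overlap into the chromosome arms, repeats into the middle
  third (a "pericentromeric" proxy).
* Methylation truth is piecewise-constant over 200 bp blocks per
  context, drawn from bands that reproduce the canonical plant
  ordering: CG bimodal with a high mode at 0.60–0.95, CHG broad at
  0.02–0.80, CHH at 0.01–0.17. Planted DMRs override the block
  baseline with one that leaves room for the signed effect, so a
  hypomethylated CHH region never clips at zero and the planted
  difference is exactly the configured effect.
* Planted constitutive DMRs sit inside gene windows (so links exist
  downstream) with ≥ 400 bp separation — wider than the merge gap plus
  kernel support, so recovered regions never fuse across planted
  boundaries. Induced DMRs are CHH-biased (70 %), mostly
  hypermethylated after stress (75 %), and mostly in the comparison
  cultivar (80 %). Default effects are 1.5× the context's calling
  threshold over 2× its minimum span — detectable but not trivial.
* Observed counts are Binomial(depth, level) with Poisson depth
  (default mean 30) independent across samples; CG strand pairs are two
  independent draws sharing a true level.
* SNPs inside each planted constitutive DMR (3 per DMR) carry the
  negative methylation–dosage coupling: with probability
  `dosage_coupling_prob` (default 0.8) the cultivar hypomethylated
  there receives per-SNP dosages strictly above the other cultivar's,
  so the per-DMR sums are ordered before sampling noise. These SNPs
  always pass the quality filters; background SNPs include low-QUAL,
  out-of-depth, monomorphic, missing-genotype and multi-allelic records
  so the filters are exercised. Alternative alleles are
  transition-biased (80 %), matching deamination-dominated divergence.
* The DE table gives planted DEGs |log₂FC| ∈ [1.5, 4] and FDR < 0.01 and
  plants boundary rows (log₂FC exactly 1.0; FDR exactly 0.05) among the
  non-DEGs to exercise strictness. DEG assignment is independent of DMR
  placement and direction, so no direction × regulation coupling exists
  unless planted.

All randomness flows through one `numpy.random.default_rng(seed)`
stream in a fixed order, so datasets are bit-reproducible.

**What passing tests show — and don't.** Recovery ≥ 0.9 and a ~0 null
rate demonstrate the caller's correctness and calibration under the
generator's assumptions: crisp region boundaries, exchangeable
replicates, Poisson-Binomial noise, no bisulfite-conversion error, no
coverage dropout structure, no linkage among SNPs. Real WGBS violates
several of these (replicate dispersion, mappability gaps, conversion
bias), so these numbers are statements about the method, not forecasts
of field performance.

## Problem sizes

The reference scenario is a 1 Mb genome (≈ 500 k cytosine records per
sample) at depth 30 with 3 replicates — large enough that every context
has thousands of regions of each kind, small enough that the full
recovery study (20 planted + 20 null seeds) and the acceptance script
run in minutes on one CPU. Counts scale linearly for larger genomes;
the caller's cost is dominated by two dense convolutions per context
and chromosome.

## Known limitations

* Fisher-on-pooled-counts ignores replicate dispersion (above).
* The smoothed-curve candidate definition can split a true region at an
  internal cytosine desert wider than the kernel support; the fragments
  are then individually size-filtered. This is visible in the recovery
  suite as the occasional missed planted region (~4 %).
* The MAF filter is applied to the two-cultivar dosages, not to a
  population; with two tetraploid samples the frequency grid is coarse
  (multiples of 1/8).
* Metagene bodies shorter than `n_body_bins` leave empty bins (NaN), by
  design rather than interpolation.
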