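# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Variant calling

The caller treats each site independently.  Under the null (no variant),
the alternate count at a site of depth `d = a + r` is
`X ~ Binomial(d, e)` where `e` is the per-base error rate after
alignment and duplicate removal.  A site is a candidate when
`a >= min_alt` and the exact upper tail `P[X >= a] < alpha`.

Defaults and rationale:

* `error_rate = 1e-3` — typical post-filter substitution noise for
  hybrid-capture Illumina data; at this rate a 0.2% VAF variant is
  separable from noise once depth exceeds a few thousand reads.
* `min_alt = 5` — a count floor so that no p-value, however small, can
  promote a site supported by a handful of reads.
* `alpha = 1e-6` — with ~3.7x10⁵ bases in a typical panel, the expected
  number of false-positive sites per sample stays below 1.
* Germline filtering: a call is germline when the matched blood sample
  shows VAF >= `normal_vaf_max` (0.01) **and** alternate count >=
  `normal_alt_max` (3), both inclusive.  The conjunction keeps
  low-coverage normals from flagging somatic calls on one stray read,
  while still catching heterozygous sites (~0.5 VAF) at any usable depth.
  A tumour sample with no matched-normal rows at all is an error; a
  site merely absent from the normal table counts as zero normal
  coverage and stays somatic.

The VAF convention is `a/(a + r)` throughout (depth-relative, the
standard convention); multiplying by 100 gives the percentage form used
in reports.  Coverage QC reports the arithmetic mean depth and the
fraction of sites at or above a threshold (default 100x).

## Copy number

Per-exon mean depths are modelled as proportional to
(copy number / 2) x capture efficiency x library size.  Library size is
removed by dividing each sample's exon depths by its total on-target
depth; capture efficiency is removed by dividing by the panel-of-normals
reference (per-exon median across >= 3 normals, each itself total-depth
normalized).

The resulting ratios are then re-centred by the **median of per-gene
median ratios**.  Re-centring is needed because a strong amplification
inflates the tumour's total depth and would otherwise drag every
copy-neutral exon's ratio below 1.  The centre is taken over genes
rather than exons because amplification is a gene-level event: a heavily
amplified multi-exon gene can account for a large share of panel exons
while being one of few affected genes, and an exon-level centre would
then land in the amplified tail (observed as a ~20% downward bias on a
60-exon amplified gene in development experiments).  The assumption is
that most panel genes are copy-neutral; a single-gene panel cannot be
re-centred meaningfully.

The gene summary is `A = 2 x median(exon ratios)` — the median is robust
to single-exon dropout; a mean summary is available via
`summary="mean"`.  `A` is on the copy-number scale (diploid gene = 2).
The amplification call threshold defaults to 3.0 (inclusive): reported
amplified genes in this setting span values of about 4-30 while
non-amplified genes sit at 2, so any cutoff in (2, 4) separates them;
3.0 is the midpoint on the copy-number scale.

## Digital PCR

Template molecules distribute over the chip's wells as a Poisson
process, so with `k` of `n` wells positive the mean copies per well is
`lambda = -ln(1 - k/n)` (undefined at `k = n`; a saturated chip needs
re-dilution).  Concentration is `lambda / v_p x dilution` with the well
volume `v_p = 0.809 nL`, the nominal well volume of a 20,000-well chip;
both are configurable.  The mutant-allele percentage is `100 x FAM/VIC`
(mutant over wild-type concentration), matching how dual-dye rare-allele
assays are reported; `FAM/(FAM+VIC)` is available behind a flag for
comparison with VAF-style fractions.  A sample is called positive when
its percentage reaches `fold_threshold` (default 5) times its negative
control, inclusive — the control defines the assay's background from
probe cross-talk and template-free amplification.

NGS/dPCR concordance reports the per-pair ratio (dPCR % over NGS VAF %),
a "similar" flag for ratios within [0.5, 2], and the Spearman rank
correlation across pairs.

## Pathway scoring

The scientifically load-bearing step is standardization to normal
tissue: `z_gi = (x_gi - mu_g)/sigma_g` with `mu_g`, `sigma_g` estimated
from the normal reference (ddof = 1; genes with fewer than two normal
observations or zero normal variance are excluded with a warning).  A
sample's pathway alteration score is the unweighted mean of `z` over the
gene-set genes present; missing values are dropped per sample with
`n_genes_used` recording how many genes entered the mean.  The
unweighted mean is the simplest member of the single-sample
pathway-score family; no gene weighting is applied because no weighting
scheme is identifiable from score tables alone.

Batch alignment before standardization is per-gene location-scale
matching of the target batch to the reference cohort.  Full
empirical-Bayes batch correction (ComBat-style shrinkage of the per-gene
location/scale estimates) is deliberately out of scope: with the batch
sizes involved here the shrinkage mostly matters for very small batches,
and the location-scale step already removes the systematic platform
offset that would otherwise corrupt the z-scores.  Genes with zero
target variance get a location-only adjustment; genes absent from the
reference pass through unchanged (both logged as warnings).

Group comparisons report both Welch's *t* and the two-sided rank-sum
test because the score distributions are small (4 vs 7 in the motivating
design) and neither normality nor equal variances can be checked
meaningfully at that size.  The rank-sum p-value is exact whenever the
smaller group has <= 10 samples; an exhaustive-enumeration helper
(`exact_ranksum_p`, 330 arrangements for 4-vs-7) provides an independent
cross-check.  Gene ranking uses the mutated-minus-wild mean `z`
difference, ascending (most down-regulated first), ties broken
lexicographically.

Copy-number/expression association is ordinary least squares of the HER2
z-score on the amplification value, with the Pearson correlation.

## Cohort summaries

HR-positive means ER and/or PR positive; triple-negative means all three
receptors negative; the categories may overlap, so subtype counts need
not partition the cohort.  Medians use the even-`n` convention (mean of
the central pair) — note this gives 44.5 for the bundled cohort's ages
while 45 is sometimes quoted for the same data under a different
convention.  Percentages are rounded half-up to one decimal.  Mutation
annotations like `S413L (0.01)` parse into (protein change, VAF
fraction); the parenthetical is a fraction rounded to two decimals
(sample 226's `0.22` appears to be on the percent scale instead — an
inconsistency in the source table that is preserved, not corrected).
Amplification annotations `Amp. (x)` parse to the numeric value; `None`
means non-amplified, reported at the diploid value 2.

## The synthetic-data generator

`simdata` emulates the three data modalities:

* **Panel counts.**  Per-exon depth is negative-binomial with
  `var = m + a m^2` around `depth_mean x CN/2` (tumour) or `depth_mean`
  (normal), constant across the exon's sites.  The default
  `depth_mean = 941.3` matches panel-scale mean coverage; the default
  dispersion `a = 0.02` gives a ~14% depth CV, the reproducibility of
  normalized hybrid-capture exon depths (Poisson noise alone, ~3% at
  this depth, is unrealistically tight for depth-ratio CNV testing,
  while a = 0.1 — a 32% CV — is RNA-seq-scale biological noise that no
  capture panel shows after normalization).  Alternate counts are
  binomial: `vaf + (1 - vaf) x error_rate` at spiked sites, `error_rate`
  elsewhere, 0.5 at germline het sites, which appear in both members of
  a pair at ~1 site/kb by default.  A spike at or below the error rate
  is rejected as undetectable by construction.
* **dPCR chips.**  Per-dye positive counts are
  `Binomial(n, 1 - exp(-lambda))` with `lambda` from the requested
  concentration and well volume — exactly the model the estimator
  inverts, so recovery tests are calibrated.
* **Expression.**  Normals are `N(mu_g, sigma_g^2)` per gene
  (`mu ~ U(5,12)`, `sigma ~ U(0.5,2)` on a log-expression-like scale);
  tumours share the baselines with within-group noise of 0.5 SD.  The
  HER2 gene is `baseline + slope x copy_number + noise`.  Mutated
  samples shift every gene-set gene by `pathway_effect` (default -0.5
  SD) and the designated GRB2-like gene (first of the set unless named)
  by `pathway_effect + grb2_extra` (default -0.5 + -1.5 = -2.0 SD) —
  effect sizes chosen so the pathway suppression is moderate but the
  adaptor gene's extra drop is decisive, mirroring a "most
  down-regulated gene" phenotype.  An optional location-scale batch
  effect (`x -> loc + scale x x`) applies to the tumour batch only.
  Default design: 61 normals, 7 amplified-wild vs 4 amplified-mutated
  tumours.

All generators derive every draw from one explicit seed (no global
state); identical arguments are byte-identical.  What the generator does
**not** emulate: GC/mappability structure in depth, error-rate variation
across sites and strands, FFPE artefacts, subclonal structure, dPCR well
volume variation and fluorescence misclassification, expression
mean-variance coupling and gene-gene correlation.  Passing recovery
tests therefore demonstrate estimator correctness under the stated
models, not robustness to these real-data complications.

## Recovery experiments and problem sizes

`her2seq.experiments` defines the end-to-end experiments used by the
test suite and the reproduction script:

* Caller: 1.2x10⁵ null sites at depth ~1000 (any call is a false
  positive), and 500 spiked sites at VAF 0.01, fixed depth 5000, where
  the exact binomial oracle predicts power in closed form (the fixed
  depth is what makes the closed form exact).
* CNV: 100 replicates per true copy number in {3.99, 5.39, 14.53,
  30.13} at depth 1000 — a 27-exon amplified gene (ERBB2-sized) over a
  20-gene diploid background, each replicate against a fresh 20-normal
  reference.  Gene-level precision scales as `1.25 x CV / sqrt(n_exons)`,
  so exon count is the lever that matters.
* dPCR: 500 chips at lambda in {0.005, 0.05, 0.5}.
* Pathway: 100 replicates of the 4-vs-7 design.  Copy number is held
  fixed at 12 across the cohort in these experiments: the HER2 gene
  belongs to the scored set and its expression tracks copy number, so
  per-sample copy-number variation would inject variance unrelated to
  the expression effect under test (with it, the HER2 gene spuriously
  out-ranks the GRB2-like gene in ~20% of replicates).

These sizes keep each experiment in the seconds-to-tens-of-seconds range
while leaving Monte-Carlo error well below the decision margins.

## Numerical conventions and degenerate inputs

* Sites are 1-based (VCF-style) in count tables and outputs; panel
  regions are BED 0-based half-open, so position `p` is in `[s, e)` iff
  `s < p <= e`.
* `poisson_lambda` uses `log1p` for accuracy at low occupancy; a
  half-positive chip gives `ln 2` exactly in floating point.
* Binomial tails use the survival function at `a - 1` (inclusive tail).
* Thresholds are inclusive everywhere (`>=`): germline filter,
  amplification call, dPCR positivity.
* Uncovered sites (`a + r = 0`), empty depth lists, saturated chips,
  zero wild-type concentration, fewer than 3 normals, dead reference
  exons, zero copy-number variance and groups smaller than 2 all raise
  errors rather than return sentinel values.
* Indels are handled through the same alt/ref count interface as
  substitutions; no realignment is attempted.

## Known limitations

* The caller is single-sample with a fixed global error rate; it does
  not model site-specific error, strand bias or mapping artefacts, and
  is not a substitute for a pairwise-likelihood somatic caller on real
  data.
* Copy-number estimation has no segmentation, GC correction or
  allele-specific resolution, and assumes a mostly copy-neutral panel.
* The expression stage assumes the normal reference and (after
  alignment) the tumour batch are on a common scale; it cannot rescue a
  batch effect that is not location-scale per gene.
* Survival analysis is out of scope: per-patient follow-up times are not
  part of the bundled tables.
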