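# Methods

This note documents the statistical models, the synthetic-data generator, and
the numerical and design choices behind `clinepar`.

## Differential expression model

Counts are converted to log₂-CPM, `log2((count + c) / (libsize + 2c) * 1e6)`
with prior count `c = 0.5` (a standard stabilizer; configurable). For one
species × tissue, the latitudinal contrast is a two-group comparison of the
low-latitude against the high-latitude population's replicate pools:

* `logFC = mean(low) − mean(high)` on log₂-CPM, so **negative logFC means
  lower expression in the low-latitude population**. This orientation is
  used consistently by the parallelism, enrichment and direction statistics.
* Per-gene pooled residual variances `s²_g` with `d_g = n₁ + n₂ − 2` df are
  shrunk toward a scaled inverse-χ² prior with hyperparameters `(d₀, s₀²)`
  fitted by method of moments on `log s²_g`: the excess of
  `var(log s²)` over `trigamma(d_g/2)` estimates `trigamma(d₀/2)`
  (Newton-inverted; `d₀ = +∞` when the excess is ≤ 0, i.e. no more spread
  than chi-square sampling noise explains), and `s₀²` comes from the mean of
  the digamma-corrected log variances. If all variances are identical the
  prior is a point mass at that variance.
* The moderated statistic `t = logFC / sqrt(s̃²(1/n₁+1/n₂))` with
  `s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g)` is referred to a *t* distribution with
  `d₀ + d_g` df; when `d₀ = +∞` the normal (large-df) limit is used, and
  `d₀ = 0` reproduces the ordinary pooled two-sample *t* exactly (a tested
  limit).
* Multiple testing: Benjamini–Hochberg step-up; DE means adjusted *P* ≤ 0.1.

No precision weights and no mean–variance trend are fitted. With three
replicate pools per population the trend is barely estimable, and the
constant-dispersion generator used for validation does not produce one; on
real data with a strong mean–variance relationship this simplification will
cost some power for low-count genes (a known limitation).

Expression filtering follows the median rule: a gene is expressed if its
median TPM (length-normalized within sample: rate `count/length_kb`
rescaled to a million) is strictly greater than 1 in at least one focal
population; cross-species comparisons keep orthologs expressed in every
species compared.

## Parallelism statistics

Over the joined ortholog table (one row per 1:1(:1) ortholog expressed in
all species of a comparison):

* **Shared-DE excess.** Expected sharing under independence is
  `E = N·∏(nᵢ/N)` — the mean of the null in which each species' DE labels
  are shuffled independently over the N orthologs (verified against a
  permutation oracle). The excess test is the one-sided upper tail of
  `Binomial(N, ∏nᵢ/N)` at the observed shared count: the null of interest
  is "no excess", and the binomial approximation to the permutation null is
  slightly conservative (measured: ~0% of null seeds at p ≤ 0.05).
* **Direction concordance.** Shared direction means all compared logFC share
  a sign. Exact zeros are ties, excluded with a warning (a measure-zero
  event for continuous estimates). The concordance test is a one-sided
  binomial with the transcriptome-wide concordant fraction as the null
  proportion. "Percent higher in the high-latitude population" is the
  fraction of same-direction shared-DE genes whose common sign is negative
  (per the logFC orientation above).
* **logFC correlation.** Spearman's ρ (average ranks on ties, *t*
  approximation for *P*), computed over all expressed orthologs of a pair.

## Tissue bias

τ is computed on `log2(TPM + 1)` per tissue; genes with zero expression
everywhere are excluded and flagged. The organ-vs-whole-male classifier
declares a gene organ-biased when, on one gene universe: the
(whole male − organ) log₂ contrast is at or below the organ cutoff (defaults
−3.59 for the accessory gland, −0.46 for the testis), adjusted *P* ≤ 0.01,
organ median TPM ≥ 1 (AG) or ≥ 5 (testis), average expression > 0 (AG,
strict) or ≥ 0 (testis), and the (whole male − other organ) contrast is
≥ +1. The contrast orientation makes organ-enriched genes strongly negative,
which is the only orientation under which those cutoff signs cohere. The
minimum-TPM condition is evaluated on the organ's median TPM across all
focal samples. `calibrate_thresholds` grid-searches the logFC (and TPM)
cutoffs to maximize Jaccard overlap with a τ ≥ 0.9 call set, breaking ties
toward stricter cutoffs; re-applying the returned thresholds reproduces
their own call set (idempotence, tested). For species-pair analyses a gene
counts as tissue-biased if biased in either or both species.

## Gene-class enrichment

2×2 tables (class × DE, or class × logFC sign) are built over the expressed
universe; zero-logFC genes join neither sign class (warned, total reduced).
Fisher's exact test is two-sided by summation of hypergeometric
probabilities no larger than the observed table's (the R convention; this is
what makes balanced tables return exactly 1.00). The implementation
delegates to `scipy.stats.fisher_exact` and is cross-checked in the tests
against a from-scratch enumeration of all tables with the observed margins.
The reported odds ratio is the unconditional sample estimate `ad/bc`.
Summary percentages are reported to one decimal; the fold printed in
formatted reports is the ratio of those rounded percentages (matching how
such tables are conventionally printed), while full-precision values are
always written alongside.

## Expression branch lengths (LED)

Each gene contributes a four-point profile `e = log2(median TPM + 1)` for
(high-latitude focal, low-latitude focal, outgroup 1, outgroup 2); the
pseudo-count 1 matches the rest of the pipeline, and per-gene distances are
absolute differences. Under the fixed topology ((out1,out2),(focal1,focal2))
the terminal branch to a focal population is the three-point formula
`(d(F,o) + d(F,F′) − d(F′,o))/2` per outgroup `o`, floored at zero (branch
lengths are non-negative by definition; for collinear profiles the floor
never binds and the estimate equals the minimal-length line embedding of the
quartet, which the tests verify against a brute-force Steiner oracle to
1e-12), then averaged over the two outgroup rootings — both outgroups are
treated symmetrically rather than taking a min or max. Set contrasts
(DE vs. not, biased vs. not, focal vs. focal) use Welch's unequal-variance
*t*-test; two zero-variance identical vectors yield a NaN-flagged *P*.
Branch lengths are invariant to adding a constant to all four profile values
(tested).

## The synthetic-data generator

`SimConfig` defaults emulate the target study design: 3 species × 2 focal
populations × 2 tissues × 3 replicate pools, plus 2 outgroup populations per
species for rooting, ~8000 genes of which 80% are 1:1(:1) orthologs.

* **Counts.** Gene abundance `q_g = 2^baseline` with baseline uniform on
  log₂ [1, 9]; a sample's expected counts are
  `libsize · q_g·len_g / Σ q·len` (reads proportional to transcript
  abundance × length, so TPM recovers `q`); libraries uniform on
  [5e6, 1e7]; counts are negative binomial with constant size `r = 100`
  (variance `μ + μ²/r`, i.e. overdispersion 0.01 — the scale appropriate
  for replicate pools that each average 12 isofemale lines, and small
  enough that planted effects are recoverable from the counts, which the
  recovery invariants below require).
* **Effects.** Per tissue, ortholog rows receive true latitudinal log₂
  effects (low minus high latitude) from an equicorrelated multivariate
  normal across species: SD `effect_sd` (default 0.25, which yields
  percent-DE in the mid-teens to low twenties at the default problem size,
  the scale observed in comparable organ studies), pairwise correlation
  `cross_species_corr` (default 0.46). `de_direction_bias` (the probability
  an effect is negative) is implemented as a mean shift
  `−sd·Φ⁻¹(bias)` so the sign skew does not distort the configured
  correlation. A `shared_outlier_fraction` of ortholog rows instead gets a
  common ±`outlier_effect` across species (sign negative with probability
  `de_direction_bias`) — the shared-outlier mode of parallelism. Private
  (non-ortholog) genes get independent effects. Effects apply to the
  low-latitude population mean; outgroup populations sit at the ancestral
  (high-latitude) mean plus independent N(0, `outgroup_drift_sd`) drift per
  gene.
* **Classes.** Membership probability is `class_base_rate` (0.03), times a
  relative risk (default 3 for the "Sfp" label, capped at 0.95) for genes
  that are outliers or have |effect| > max(2·effect_sd, 0.5).
* **Streams.** Shared quantities (ortholog baselines, lengths, joint
  effects, outlier choices) come from one RNG stream; each species' private
  genes and counts come from a per-species stream derived from the master
  seed by fixed offsets, so adding a species does not perturb another's
  draws. Same seed → byte-identical output files.

What the generator does **not** emulate: batch effects, isoform structure, a
mean–variance dispersion trend, correlated expression between genes,
unbalanced replicate loss, or cross-species differences in gene length and
annotation quality. Passing tests therefore demonstrate correctness of the
statistical machinery under the design's sampling model, not robustness to
those real-data complications.

### Validation experiments and problem sizes

The test suite runs the generator at reduced sizes chosen to keep the full
suite in the tens of seconds while leaving Monte-Carlo error well inside the
asserted bands:

* **Correlation recovery** (configured cross-species correlation 0.46,
  8000 orthologs, 3 vs 3 replicates, 20 seeds): run at effect SD 1.0. A
  recovery experiment must be signal-dominated; at smaller effect scales the
  estimated-logFC Spearman ρ measures noise attenuation on top of the
  intrinsic Spearman-vs-Pearson gap for bivariate normals
  (ρ_S = (6/π)·asin(r/2) ≈ 0.443 at r = 0.46) rather than the generator's
  parameter. Measured recovery: ρ ≈ 0.41–0.44.
* **Null calibration**: no-effect simulations for BH false-call control and
  for the LED branch-length symmetry; a no-*sharing* simulation
  (correlation 0, no outliers, effects present) for the shared-DE
  enrichment test, since with no effects at all the test is vacuously 1.
* **Planted-sharing detection**: 2% shared outliers on a no-effect
  background at 5000 expressed orthologs — the outliers are then the only
  sharing channel and detection is essentially certain (p ≈ 1e-120); on a
  background of dense independent effects the same planted fraction is
  diluted by chance sharing of independent DE calls and is not reliably
  detectable, which is why the detection experiment is defined this way.

## Degenerate inputs and tie-breaks

* All-zero count columns yield all-zero TPM columns (no NaNs).
* Genes with zero variance across all samples get `t = 0`, `p = 1`.
* BH is implemented as the standard step-up with a stable sort; adjusted
  values are monotone in the raw ranks and capped at 1.
* Ties in calibration grid search break toward stricter thresholds.
* 1:1 violations in ortholog maps reject the whole file, naming the gene.

## Known limitations

* The moderated-*t* engine intentionally omits voom-style weights and the
  mean–variance trend; it is validated against its own oracles and
  simulations, not against any external tool's output.
* The binomial constructions for the excess and concordance tests are one
  of several defensible choices; with few shared DE genes the concordance
  test is low-powered and its null proportion is itself estimated.
* Flooring negative three-point branch estimates at zero biases mean LED
  slightly upward for noisy, non-additive profiles.
* Tissue-bias transfer across species inherits any body-size or
  organ-composition differences between species; the classifier does not
  correct for them.
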