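# Methods

This note documents the models implemented in `replomics`, the assumptions
they make, the defaults and why, and what the synthetic-data validation does
and does not demonstrate.

## Cohort selection

Relative weight change is computed in percent of baseline body weight per
month, `100 * (W_followup - W_baseline) / W_baseline / months`.  Subjects
losing more than 1% per month form the weight-loss group; subjects who never
lost weight and gained less than 0.1% form the stable (no-weight-loss)
group; everything in between is left unassigned.  Both thresholds are
configurable.  The stable-weight bound is interpreted per month, on the same
timescale as the loss criterion, with a lower bound of zero (no loss); the
symmetric reading keeps the two criteria comparable.  Subjects whose
recorded weight series is exactly constant are excluded before grouping:
repeated identical values are the signature of a stale self-reported weight
carried forward, so the rule uses exact equality rather than a variance
tolerance.  Series with fewer than two entries cannot be assessed and are
kept with a flag.

## Replication-rate estimation

**Model.**  A bacterial population replicating bidirectionally from a
single origin has expected read depth proportional to `PTR^(1 - x)`, where
`x` in [0, 1] is the relative distance from the origin along a replichore
and PTR is the peak-to-trough coverage ratio.  On the log2 scale this
gradient is linear in position; because a contig's orientation and position
relative to the origin are unknown, the estimator works on *sorted* binned
coverage instead of positional coverage, where the same gradient appears as
a linear trend of log2 coverage against rank.

**Procedure.**  Per-base depth (from coordinate-sorted alignments counting
primary, non-supplementary mapped reads, or from a depth TSV) is averaged
into 100-bp bins (trailing partial bins dropped, so no downward-biased edge
bin enters the fit), smoothed by a 50-bin centered sliding-window mean
(5,000 bp; edge windows truncated to the available bins), sorted ascending,
trimmed by 5% per tail, log2-transformed (non-positive bins dropped and
counted), and regressed by OLS against rank rescaled onto [0, 1] over the
original pre-trim rank range, i.e. rank *i* of *n* maps to `i/(n-1)`.  The
fitted log2 span across [0, 1] is the slope *m*; `rate = 2^m`.  Constant
profiles give rate exactly 1 with the coefficient of determination reported
as undefined (NaN).  Fits with fewer than 10 usable bins, or all-zero
coverage, are refused with a reason rather than reported.

**Eligibility.**  Only contigs of at least 11,000 bp with unsmoothed mean
binned coverage of at least 2× are fitted (both thresholds inclusive and
configurable; a looser 5,000 bp tier governs which profiles are extracted
at all).  Filters are applied to unsmoothed bins.

**Interpretation.**  Rates are reported per contig as observed *local*
gradients.  No extrapolation to whole-genome peak-to-trough ratios is
attempted: assembled contigs carry no origin/terminus annotation, and a
contig spanning a fraction of a replichore sees only that fraction of the
full gradient.  A consequence worth knowing when validating against
simulations: a noise-free contig spanning a full replichore sampled at *n*
bins recovers `PTR^((n-1)/n)`, not PTR exactly — the first-to-last bin span
of a discretised gradient — which is a < 1% effect for the contig sizes
used here.  Heavy smoothing relative to contig length also compresses the
observed span (the truncated edge windows pull the extremes toward the
interior); at the default 50-bin window the effect is material for contigs
near the 11 kb minimum (~7% low at 110 bins) and negligible by ~500 bins.
Simulation-based checks therefore use 50 kb single-replichore contigs,
where both effects are well inside the ±0.15 recovery band.

**QC.**  `min_r2` optionally gates estimates on fit quality; the default is
off (report-only), since no fit-quality cutoff is part of the method's
contract.

**Aggregation and testing.**  Per sample and phylum the unweighted mean of
contig rates is reported (weighting by length or coverage is available but
not default; the unweighted mean is the plain reading of an "average
replication rate").  Contigs without a phylum-level classification pool
under "NA", and a per-sample overall mean across all contigs is emitted
under the label "all".  Group differences are tested with OLS of
`mean_rate ~ group + age + baseline_bmi`; for a binary group the t test of
the adjusted group coefficient is identical to the covariate-corrected
ANOVA F test of that factor.  Per-sample means are the default unit of
analysis (a per-contig mode exists but treats correlated contigs as
independent and is not default).  Constant covariates are dropped from the
design rather than aliasing the intercept, which reduces the model to the
classical pooled-variance two-sample t test when age and BMI carry no
information.

## Feature preparation

* **Metabolites** — per batch, each metabolite is divided by its
  within-batch median over study samples (batch median becomes 1) and then
  by the mean of the scaled values in that batch's quality-control samples
  ("average" is taken as the mean).  Missing cells are imputed as the
  metabolite's minimum observed normalized value across the cohort, then
  everything is log-transformed.  QC samples are removed from the output;
  a batch without QC samples is an error.
* **Proteins** — features with ≥ 5% missing samples are dropped; remaining
  missing cells take the feature's observed minimum; log transform.
* **SRM panels** — within-subject change is `log(followup) − log(baseline)`
  per protein, requiring positive light/heavy ratios.
* **Gene clusters** — ORF counts are summed per annotation term (KO);
  unannotated ORFs pool under a reserved `unannotated` row that preserves
  library sizes but is excluded from cluster-level tests and richness.
* **Log base** — natural log throughout (configurable); every downstream
  t statistic is invariant to the base.
* **Size factors** — the zero-tolerant median-of-ratios rule: per-feature
  reference `g_i = exp(Σ_{c_ij>0} log c_ij / n_samples)` (the denominator
  counts all samples), per-sample factor = median of `c_ij / g_i` over
  features positive in both.  Factors are rescaled to geometric mean 1,
  fixing the scale the construction leaves free so fixtures and offsets are
  reproducible.
* **Rarefied richness** — one seeded multivariate-hypergeometric draw of
  100,000 assigned-cluster reads per sample (sampling without replacement),
  counting clusters still observed.  Samples below the depth are excluded
  with a warning.  A single draw matches the single-downsampling contract;
  an averaged-repeats variant can be built on the same primitive.

Imputation never alters an observed cell; cluster aggregation conserves
per-sample totals.

## Dual-regression association framework

Subjects with high baseline BMI tend to show larger weight changes
(regression to the mean), so baseline-BMI structure masquerades as
weight-loss structure in naive models.  Each feature is therefore fitted
twice:

* weight-loss model: `y ~ group + baseline_bmi + age + sex`, target =
  group indicator;
* BMI model: `y ~ baseline_bmi + age + sex`, target = baseline BMI, no
  group term.

No interaction terms are fitted (sex-by-group cells would be tiny at these
cohort sizes).  Continuous log-scale analytes and ordinal diet scores
(treated as numeric responses) use per-feature OLS with no information
shared across features — equivalent to a moderated linear-model fit with
shrinkage disabled.  Counts use per-feature negative-binomial (NB2)
log-link regression with `log(size factor)` offsets; the dispersion is
estimated per feature by profile likelihood over alpha given the current
GLM means (Poisson fit as the seed, two refit rounds), with a Pearson
method-of-moments estimate as fallback.  This deliberately omits the
empirical-Bayes dispersion shrinkage of full differential-abundance
machinery; the cost is noisier per-feature dispersions at small n, and the
consequence is bounded by the null-calibration check below.  All reported
t (or Wald pseudo-t) statistics are exactly `coef / se`; OLS p values use
the t reference with residual degrees of freedom, NB Wald p values the
normal reference, two-sided throughout.  Sex enters as a 0/1 indicator
(female reference by default; the choice only flips the coefficient sign).

BH adjustment is applied within each data type, and features are classed
`bmi_only` / `wl_only` / `both` / `neither` by comparing the two FDR values
to a threshold (default 0.05; configurable per data type).  Zero-variance
features are reported with coefficient 0, p 1 and a flag rather than
silently dropped; all-zero or non-converged count features are flagged and
excluded from the FDR set.  The Pearson correlation between the two t
vectors summarises how orthogonal the two association axes are.

Supporting analyses: the SRM change model (weight-loss model on log-ratio
changes, BH within the panel, default FDR threshold 0.1); the two richness
models (`richness ~ bmi + sex + age` and `richness ~ group + bmi + sex +
age`); unadjusted Welch t tests and marker-by-marker Pearson matrices for
baseline group description; and paired t tests for baseline-vs-follow-up
chemistries.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with truth
tables sufficient to score downstream results without reaching into
generator internals, and is a pure function of its config including the
seed.

* **Coverage** — expected depth `mean_depth`-scaled `PTR^(1-x)` with `x`
  the circular distance from the origin over half the genome length
  (exponential-in-distance, the regime in which the sorted-coverage slope
  estimator is consistent); Poisson per-base noise or exact expectation;
  left-to-right fragmentation into contigs.
* **Cohort** — BMI ~ N(30, 5) kg/m², age ~ N(50, 10) y, sexes balanced,
  105 subjects with 48/105 in the weight-loss group by default, matching
  the emulated study conditions.  Weights consistent with each subject's
  group are generated (loss rates uniform on [−3, −1.05] %/month, stable
  rates on [0, 0.095]) so the selection rules re-derive the simulated
  labels; optional stale-scale subjects exercise the zero-variance
  exclusion.  Each feature follows `eta = intercept + beta_bmi*(BMI-30) +
  beta_wl*group + beta_sex*sex`: continuous features add Gaussian noise to
  eta; counts are NB2 draws with mean `library_factor * exp(eta)`
  (library sizes uniform over 150k–400k reads, exercising the size-factor
  path); ordinal diet scores cut a latent Gaussian at its equal quantiles
  into the 0–8 scale.

**What passing simulation checks does and does not show.**  The generator
realises exactly the model families the estimators assume (exponential
coverage gradients, log-linear covariate effects, NB2 counts, latent-
Gaussian ordinals).  Recovery and calibration on these data demonstrate
correctness of the implementation and internal consistency of the
inferential contract — not robustness to real-data pathologies such as
GC-coverage bias, strain mixtures, repeat-driven coverage spikes,
compositional effects with many correlated features, batch structure
beyond the modelled QC scaling, or misreported weights beyond the
stale-scale pattern.

## Numerical and validation choices

* Bin coordinates are 0-based half-open internally; depth TSVs are 1-based.
* The symmetric trim drops `floor(trim_fraction * n)` bins per tail.
* NB dispersion is bounded to [1e-8, 100]; at the lower bound the NB GLM is
  numerically a Poisson regression (verified to 1e-3 against a direct
  Poisson fit).
* Validation conditions were sized once from variance considerations:
  rate-recovery checks use 200 replicates per gradient level on 50 kb
  single-replichore contigs at 20× depth; NB null calibration uses 20
  cohorts of 1,000 null count features at n = 25; NB effect recovery
  checks the systematic bias (mean coefficient error over marked features
  and cohorts — at n = 25 and dispersion 0.1 the per-feature Wald SE is
  ~0.13–0.16, so per-feature absolute error is dominated by sampling noise
  and is not a meaningful bias measure).  Dual-model orthogonality pools
  20 cohorts because the off-target model inherits a per-cohort leak of
  order `t_detect / sqrt(n)` from the sample group–BMI correlation — an
  intrinsic property of fitting the BMI model without the group term, not
  an implementation artefact.
* Effect features are kept a minority (10%) in count-recovery simulations;
  median-of-ratios normalization absorbs part of any effect shared by half
  the features, which is a property of the normalization, not a bug.

## Known limitations

* Contig rates are local gradients; comparing rates across contigs of very
  different lengths conflates gradient span with contig span.
* Per-feature NB dispersion at n ≈ 25 is noisy; borderline calls near the
  FDR threshold should not be over-interpreted.
* Ordinal diet scores are modelled as numeric responses in OLS, as in the
  emulated analysis; a proportional-odds model would be the stricter
  treatment.
* The zero-variance exclusion assumes weights are recorded values, not
  rounded re-measurements; heavy rounding of genuinely stable weights
  would be excluded too.
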