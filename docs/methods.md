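# Methods

## The model

`epiclock` predicts chronological age from RRBS methylation fractions at a
sparse set of CpG sites. The target is `y = log(age_weeks + 3)`; the
3-week offset keeps the transform defined for newborns and allows
pre-birth predictions after inversion (`age = exp(ŷ) − 3`). Natural
logarithms are used throughout, consistently with the exponential
back-transform.

Training pipeline, in order:

1. **Site intersection.** Only sites with ≥ 5 reads in *every* training
   sample enter the model, so the clock transfers to any RRBS study that
   covers the same core site set. Sex chromosomes are excluded so the
   clock is not sex-specific, and chrM is excluded because mitochondrial
   bisulfite conversion is unreliable.
2. **Quantile normalization.** The reference distribution is the mean of
   per-sample order statistics; each sample's values are replaced by
   reference values at their within-sample ranks, ties receiving the mean
   of the tied reference values. Normalization is fit on training samples
   only and the reference is stored in the model (joint normalization of
   train and test would leak information across the split).
3. **Standardization.** Per-site mean 0, sample sd 1 (n−1 denominator);
   zero-variance sites are reported and dropped.
4. **Elastic net with double-loop CV.** The penalized objective matches
   glmnet's: `(1/2n)‖y − Xw‖² + λ(α‖w‖₁ + (1−α)/2 ‖w‖²)`. The mixing
   parameter α is searched over {0, 0.05, …, 1.0} (21 points); for each α
   the λ path is 40 log-spaced values from the data-driven
   `λ_max = max|Xᵀy| / (n·max(α, 10⁻³))` down to λ_max/100 (10⁻⁴ for
   near-ridge mixings). Inner 10-fold CV picks (α, λ) by mean squared
   error, ties breaking toward stronger regularization then smaller α;
   outer 10-fold CV reports held-out MSE; the final weights are refit on
   all samples. Folds are seeded and dealt round-robin within dataset
   strata so no fold is confounded with one data source. Coordinate
   descent (scikit-learn's path solver) is used for α > 0; the pure-ridge
   path is solved exactly by SVD.
5. **Quadratic calibration.** The raw score `x = Σ βᵢzᵢ` (no intercept —
   the quadratic absorbs it) is mapped to log age by least-squares
   `log(age+3) = a·x² + b·x + c`. A quadratic rather than a line absorbs
   the mild curvature left by regularization shrinkage at the extremes of
   the age range.

## Single-sample prediction

A new sample's fractions at the model sites are mapped by within-sample
average rank onto the stored reference quantile function (linear
interpolation at quantiles `(r − ½)/m`), z-scored with stored means/sds,
and combined into `x`. This makes a prediction independent of whatever
other samples are processed in the same batch.

Because this single-sample mapping ranks only the model's own sites
(whereas training normalization ranked the full intersection), the stored
per-site means/sds and the calibration are themselves computed *through
the predict-time mapping* on the training samples, after site selection.
The two scales differ only by a monotone re-ranking that the calibration
absorbs, and the design buys an exact invariant: a training sample pushed
through the serialized model reproduces its in-training fitted value
bit-for-bit.

Sites below the coverage floor are missing. Policy `error` aborts listing
them; `mean_impute` substitutes the training mean (z = 0) with a warning
and refuses when more than 20% of model sites are missing (an engineering
guard — beyond that the score is dominated by imputation). If a query
score lands where the calibration quadratic is non-increasing
(`2ax + b ≤ 0`), the prediction is returned with a warning, never clamped
silently.

## Screening statistics

Correlations are Spearman's rho on average ranks, computed against age in
days. P-values use the exact permutation null (enumerated, cached per
rank multiset) for n ≤ 9 — tissue-specific analyses can have as few as 4
samples, where the t-approximation is poor — and the t-approximation for
larger n. Sites with fewer than 4 usable samples or zero variance yield
no result. "Nominal" means p < 0.05 and "significant" means q < 0.05.

Q-values follow Storey: `π₀(λ) = #{p > λ}/(m(1 − λ))` over
λ ∈ {0.05, …, 0.95}, smoothed by a cubic polynomial and evaluated at
λ = 0.95; estimates outside (0, 1] fall back to π₀ = 1, which makes the
procedure Benjamini–Hochberg-equivalent. The adult-only (newborn-excluded)
reanalysis and the cross-tissue sharing counts expose their p-thresholds
as parameters rather than hard-coding conclusions.

The scarcity t-tests compare each significant class (positive/negative)
against the background with Welch two-sample t-tests, Bonferroni-corrected
over the number of classes; the grouping is an interpretation choice, as
is the two-sided alternative of the binomial enrichment test. The
scarcity window defaults to 200 bp per the defining formula, with the 1 kb
variant available as a parameter.

## Coordinates

Coverage files and the internal matrix are 1-based (start == end per
CpG, strand-merged). BED inputs (feature annotations, region sets) are
0-based half-open; a site at 1-based position p belongs to `[start, end)`
iff `start ≤ p − 1 < end`. The conversion happens once, at the BED
boundary. Chromosome dialects ("1" vs "chr1") are normalized to an
explicit convention (default: `chr` prefix).

## The synthetic-data generator

The generator emulates the statistical structure the clock assumes, not
sequence-level reality. Defaults mirror a four-tissue design with
newborn, 14-, 27- and 41-week animals:

* per-site baselines are drawn from a three-component logit-normal
  mixture (40% low ≈ 6%, 40% high ≈ 92%, 20% intermediate — the bimodal
  profile RRBS produces by enriching CpG islands), then shifted by a
  numerically calibrated constant so the global mean is 45% in adults;
* newborn samples receive a global logit shift calibrated so their global
  mean is 43% (this also reproduces the observed excess of positive age
  correlations);
* tissue signatures are per-site logit offsets with sd 0.4;
* 10% of sites (default) get monotone trajectories, linear on the logit
  scale in `log(age + 3)` with slope ±1.0 (signs balanced 50/50), centred
  at the mean log-age so the global level stays stable. The logit-linear
  shape mirrors the clock's own target transform, making parameter
  recovery well-posed; the generative form is this package's choice;
* coverage is negative-binomial (mean 30, variance = μ + 0.3μ²,
  motivated by the dispersed per-site depths of real RRBS libraries) and
  methylated counts are beta-binomial (concentration 80) around each
  sample's true fraction.

What the generator does **not** emulate: genomic clustering of CpGs into
islands (positions are uniform per chromosome), batch/dataset effects,
bisulfite-conversion error, non-CpG methylation, age-dependent variance
changes, and correlated neighbouring sites. Tests passing on this
generator therefore demonstrate the pipeline's statistical correctness
under its assumed model, not robustness to every artefact of real data.

### Null scenarios

A calibration check of the screen needs an *exchangeable* null, which is
stricter than "no planted sites": the newborn global shift is a genuine
age signal at every site, and balanced tissue signatures deterministically
absorb variance orthogonal to age, which attenuates pooled rank
correlations and makes the screen conservative (empirical type-I error
0.02–0.04 at nominal 0.05) without being anti-conservative. Direct
simulation on iid data (including tied ages and extreme methylation
fractions) shows the Spearman implementation itself is exactly
calibrated. Null-calibration tests therefore disable both the newborn
shift and the tissue signatures; the conservatism under tissue structure
is a documented property of pooled screening in balanced multi-tissue
designs.

## Region clocks

Region values are unweighted means of member-CpG fractions (coverage
weighting optional); a region with no covered CpG in a sample is missing,
and regions with no CpGs anywhere are dropped with a reported count.
Width-1 regions are an exact identity wrapper over the site matrix. The
region model is the same pipeline with the mixing parameter fixed to 0
(ridge), since externally defined region sets should not be pruned by the
model. The random-region null samples k regions without replacement —
regardless of coverage, dropping incomplete regions before training and
reporting the count — and records the held-out median absolute error per
replicate. Liftover is upstream: region coordinates arrive as BED.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full study at 2000
sites and 64 training / 32 held-out samples (4 tissues × 4 ages × 4 + 2
replicates), with 50 random-region null models — sizes chosen so the
complete double-loop CV (21 α × 40 λ × 10 × 10 folds) finishes in a few
minutes on one CPU while leaving every stage's statistical behaviour
observable. Coordinate descent uses tolerance 10⁻⁴ with at most 2000
iterations; CV fold assignment, site sampling and all count draws are
driven by explicit seeds, and identical seeds reproduce outputs
byte-for-byte. Degenerate inputs (empty matrices, constant sites, folds
with fewer than two samples, k larger than the region universe) raise
informative errors rather than proceeding.

## Known limitations

* The published 329-site model's weights and normalization reference are
  not redistributable here, so models built via `ClockModel.from_site_table`
  without a reference are score-level only; the package's own clocks are
  trained from data.
* Headline accuracies of the original multi-study corpus (test MAE
  3.33 weeks, correlation 0.839) require those datasets; the package
  validates the machinery on synthetic data instead.
* The exact-permutation Spearman path enumerates up to 9! pairings per
  distinct rank multiset; data with many distinct tie patterns at n = 8–9
  will be slow (cached thereafter).
* The adult-only reanalysis and enrichment tests inherit the screen's
  conservatism under strong group structure (see Null scenarios).
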