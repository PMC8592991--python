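# Methods

This note documents the models, estimators, defaults and numerical choices
implemented in `fitcage`, and what the synthetic-data experiments do and do
not demonstrate.

## Promoter calling and architecture (`ctss`)

CTSS tracks are per-base, stranded tag counts. Pooled tracks are clustered
by single linkage along each strand: consecutive CTSSs at most `max_gap`
(default 20 bp) apart join one cluster, and clusters with fewer than
`min_tags` (default 10) pooled tags are dropped. Neither parameter has a
canonical published value for this protocol; both are exposed on the API
and CLI. The dominant TSS is the argmax of pooled counts, ties broken by
the 5′-most position on the cluster's strand so the choice is deterministic
and biologically conservative (the most upstream strongest start).

The shape index is computed from pooled counts (per-sample SI would be
noisy at typical depths) over the ±50 bp window centered on the dominant
TSS: `SI = 2 + Σ p_i log2 p_i`. Its maximum is exactly 2 (singleton);
uniform-N profiles give `2 − log2 N`, so the conventional broad threshold
of −1 corresponds to initiation spread over more than 8 positions. %GC uses
the same window, case-insensitively, excluding ambiguous bases from both
numerator and denominator; windows truncate at chromosome ends. Gene
association takes the nearest same-strand annotated 5′ end within ±500 bp
of the dominant TSS; distance ties break on gene id.

TPM normalization rescales each sample to 10⁶ tags. TPM is used for
reporting only; all testing runs on raw counts with effective library
sizes.

## Differential expression (`diffexp`)

The DE stack is a from-scratch implementation of the standard count-DE
toolchain, kept deliberately minimal:

* **TMM factors.** Reference sample = the one whose 75th count-fraction
  percentile is closest to the across-sample mean. M-values (log2 ratio of
  count fractions vs the reference) are rank-trimmed at 30%, A-values at
  5%; the factor is 2^(weighted mean M) with inverse asymptotic-variance
  weights, and factors are rescaled to geometric mean 1. The implementation
  reproduces edgeR's `calcNormFactors` to ~1% on Poisson fixtures (checked
  in the test suite via Rscript as an independent oracle).
* **Common dispersion.** Counts are scaled to the geometric-mean effective
  library and rounded; the conditional log-likelihood of each promoter's
  within-group counts given their group sum (free of the mean under equal
  libraries) is summed and maximized over φ on a log grid with bounded
  Brent refinement. There is **no tagwise empirical-Bayes shrinkage**: one
  φ is shared by all promoters. This loses power when dispersion varies
  strongly across promoters, which the synthetic generator does not emulate.
* **Exact test.** For a two-group contrast on equalized libraries the
  group-A sum conditional on the pooled total follows a ratio of NB masses
  (a beta-binomial-like pmf), or Binomial in the φ→0 limit. The two-sided
  p-value is the total conditional mass of splits no more probable than the
  observed one; this converges to the exact binomial split test as φ→0.
  log2 fold changes use a prior count of 0.5 per group mean. "B vs A"
  means logFC > 0 is higher in B; "Pre to Mid" maps to A=Pre, B=Mid, and
  classification enforces the logFC sign in addition to FDR < 0.05.
* **BH** adjustment delegates to `statsmodels.multipletests(fdr_bh)`.
* **MDS** uses the leading-logFC distance (RMS of the top-500 absolute
  pairwise log2 CPM differences, prior count 0.5) and classical
  double-centering + eigendecomposition; coordinates are defined up to
  rotation/reflection.
* **Ranking** of promoters in a set scores |logFC₁| + |logFC₂| over the two
  defining contrasts (log2 scale; the natural scale is not identifiable
  from a fold-change "sum" without a convention), ties broken by id.

## Motif analysis (`motifs`)

Regions are strand-oriented −300/+100 bp windows around dominant TSSs
(minus-strand windows reverse-complemented, edge-truncated). PWMs are
column-normalized with a pseudocount when given as counts; scanning is
log2-odds against a uniform 0.25 background over both strands, with N
scoring 0. The default hit threshold is 0.8 × the motif's maximum
attainable score — there is no published threshold for this analysis, so it
is a parameter everywhere. Enrichment is a two-sided Fisher exact test on
has-hit counts, foreground vs background (the background default is the
whole promoter universe), Bonferroni-corrected across the motif library. No
E-value model or dinucleotide background is implemented.

The positional profile is the fraction of regions in which a hit covers
each TSS offset. The reported peak is the 5′-most argmax of the
**unsmoothed** curve: a sharply positioned motif of width w covers a
plateau of w offsets whose 5′ edge is the planted position, and smoothing
(centered moving average, window rounded up to odd, default 21) shifts any
plateau argmax; the smoothed curve is returned for display.

## Torpor detection (`physio`)

Day-1 recordings of each signal are fitted with a circadian harmonic
regression — intercept plus two harmonics of a 24-h period, Normal
residuals — under weakly informative priors: mesor ~ Normal(signal mean,
10), harmonic coefficients ~ Normal(0, 5), σ ~ HalfNormal(5). The exact
form of the published baseline model is not available, so the simplest
model matching a circadian baseline is used and is deliberately replaceable
behind `fit_baseline`. T_B and VO₂ are fitted independently.

The posterior is sampled exactly rather than by MCMC: σ from its collapsed
1-D marginal (the coefficient block integrated out analytically) evaluated
on a 400-point log grid spanning [σ̂/10, 10σ̂] around the OLS residual
scale, then coefficients from their conjugate Gaussian conditional given
each σ draw. This has no convergence failure mode; a split pseudo-chain
R-hat on the mesor is still attached as a sanity flag.

The outlier bound is the lower edge of the central 99.9%
posterior-**predictive** interval per time-of-day (not the credible
interval of the mean curve): torpor detection is a per-point outlier call,
so observation noise must be included. A point is torpid when every signal
recorded at that point is below its bound and the point lies in ZT 12–24
(torpor onset is around ZT-14; the window is exposed as a parameter). When
one signal is missing the recorded one decides alone. Minimal T_B/VO₂ are
plain minima over torpid points, with an absent-value marker when nothing
is labeled.

## KO phenotype model (`bayesphen`)

The model is exactly the hierarchical normal/torpor structure described in
the README, with priors: α ~ Normal(mean(Y_NORMAL), 10); β, γ ~ Normal(0,
σ_β), Normal(0, σ_γ); σ_β, σ_γ ~ Half-Cauchy(0, 2.5); σ_NORMAL, σ_TORPOR ~
HalfNormal(10) (the half-normal scale-10 prior is applied to every
non-Half-Cauchy scale in the package). All observed (line, allele) cells
share one α and are fitted jointly, as the index structure implies. T_B and
VO₂ are modeled separately.

Sampling is blocked Gibbs: given the scales, (α, β, γ) is jointly Gaussian
and drawn exactly via a Cholesky solve; each scale is then drawn from its
1-D full conditional on a 300-point log grid wide enough to cover the
Half-Cauchy upper tail. Defaults: 4 chains, 200 warmup, 1000 draws.
Simulation-based calibration (200 replicates, all parameters drawn from
their priors) gives uniform rank statistics (χ² p ≈ 0.7) for the γ
contrasts, i.e. the sampler is exact within Monte-Carlo error. An adaptive
random-walk Metropolis sampler over the same joint density is kept in the
package (`adaptive_metropolis`); it mixes poorly on the α+β ridge for the
full model (ESS ≈ 4 per 1000 draws) but is adequate for low-dimensional
models and drives the ΔΔCT estimator.

Contrasts are drawwise differences γ[g,a] − γ[g,wt], summarized by the
median and the 89% HPDI, computed as the shortest contiguous window of
sorted draws containing ⌈0.89·n⌉ of them (ties → lowest start). The
calibration tests evaluate coverage with the central (equal-tailed) 89%
interval, the quantity with a direct frequency interpretation; the HPDI is
the reporting convention. The ΔΔCT model is a two-condition Normal means
model on per-animal ΔCT (CT_target − CT_reference) with a shared σ per
organ — the minimal choice, since no richer structure is identifiable from
typical qPCR designs; negative ΔΔCT means more target mRNA during torpor.

Rank-normalized split R-hat and bulk ESS come from arviz.

## Synthetic data (`synthdata`)

The generator reproduces the statistical structure the analyses assume, at
the study's own design sizes (Pre=4, Mid=8, Post=4, HiT=4, Fed=4, Dep=4):

* **Counts.** Promoter baselines are lognormal(0, 1) shares of a
  1,000,000-tag library (about 2,000 tags per promoter at the default 500
  promoters, comparable to a deeply sequenced CAGE library distributed over
  a desk-scale promoter set); sample means are baseline × 2^effect(condition),
  renormalized to the library size (so planted effects are mildly
  compressed by composition, as in real libraries); counts are NB with
  common dispersion φ (default 0.2, a typical bulk-count value; φ=0 gives
  Poisson).
* **Tag positions.** Each promoter gets one positional profile drawn from a
  Dirichlet whose mass is a Gaussian kernel (sd 10 bp) over ±50 bp of the
  annotated TSS divided by `shape_concentration`: large values give sparse,
  singleton-like profiles (SI near 2), small values smooth broad ones, and
  ∞ is a delta at the TSS. The mapping from concentration to median SI is
  monotone (tested); the default 5.0 yields a predominantly broad promoter
  population with a narrow tail. Real CAGE tag spread is not
  Dirichlet-multinomial; this choice simply makes SI controllable.
* **Physiology.** T_B and VO₂ are circadian cosines (acrophase ZT-18) plus
  Gaussian noise on the natural scale, 240 points/day on the 6-min grid.
  Within a bout VO₂ is multiplied by the depth factor (default 0.3)
  instantly while T_B relaxes toward ambient and recovers with first-order
  kinetics (τ = 0.5 h, spun up over a lead-in day to remove the filter
  transient). Instant VO₂ entry, Gaussian natural-scale noise and the
  single relaxation constant are synthetic-only simplifications; real
  traces have slower bout entry, heteroskedastic noise and activity
  artifacts, so detection sensitivities measured here are upper bounds.
* **Phenotypes.** Direct draws from the hierarchical normal/torpor model.

Everything is a pure function of (config, seed).

## What the tests show (and problem sizes used)

The package chooses desk-scale problem sizes so the full suite runs in a
few minutes: planted-promoter recovery uses 500 promoters × 20 seeds with
20 planted |log2FC|=2 effects at φ=0.2 (recovery ≥ 80%, false-discovery
share ≤ 10%); torpor detection uses 50 bout-free animals for the null
false-positive rate (≤ 0.5% of eligible points) and 20 bout-injected
animals for sensitivity (≥ 95%); KO-model calibration uses 50 replicates at
n=10 per cell, σ=1, 2 chains × 1000 draws. These demonstrate internal
consistency — the pipeline recovers what its own generative assumptions
plant — not performance on real CAGE or telemetry data, where mapping
artifacts, batch effects, dispersion heterogeneity and non-Gaussian
physiology all bite.

## Known limitations

* No tagwise dispersion, GLM covariates or batch correction in DE.
* No CpG-island calls, enhancer prediction or bidirectional-pair detection.
* Motif enrichment has no E-value calibration; threshold choice matters.
* The baseline physiological model is intentionally simple; animals with
  non-sinusoidal day-1 behavior would need a richer mean function.
* Whether T_B and VO₂ should be modeled jointly is open; independent fits
  are implemented.
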