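# Methods

`poolgea` implements a Bayesian hierarchical analysis of pooled
population sequencing (Pool-Seq) data for genome–environment association
(GEA), together with the simulation machinery needed to validate every
stage without external data. This note records the model, the numerical
choices, and what the synthetic data do and do not establish.

## The hierarchical model

For SNP *i* and population *j* (of *J*), with haploid pool size *n_j* and
read coverage *c_ij*:

```
pi_i      ~ Beta(a, b) restricted to [maf, 1 - maf]
alpha_i   ~ N( pi_i 1 + delta_i beta_i z ,  pi_i (1 - pi_i) Omega )
x_ij      ~ Binomial( n_j, clip(alpha_ij, 0, 1) )
y_ij      ~ Binomial( c_ij, x_ij / n_j )
```

* `pi_i` is the across-population ("ancestral") reference-allele
  frequency; its Beta shape parameters default to a = 2.78, b = 0.710,
  the heavily reference-skewed shape typical of pooled SNP calls in a
  selfing plant, with a minor-allele-frequency floor of 0.01.
* `Omega` is the scaled covariance of population allele frequencies: the
  population-structure correction. Its diagonal measures drift intensity
  per population, its off-diagonals shared history.
* `alpha_i` is a **latent, unbounded Gaussian** frequency vector; only
  its value clipped to [0, 1] enters the binomial pool-sampling layer.
  The simulator clips its Gaussian draws the same way, so the inference
  model and the generator coincide exactly. This parametrization is a
  deliberate design choice: with the default Beta shapes roughly a third
  of simulated frequencies sit at fixation, and a boundary-truncated
  parametrization attenuates the inverse-Wishart update of Omega so
  badly that the estimate is *worse* than the identity matrix (measured
  Frobenius–Moonen distance 4.6 versus 2.4). Keeping alpha latent makes
  the Omega update exact and recovers the generating matrix (distance
  0.2–0.4 in the same setting).
* The association component (`delta_i`, `beta_i`, covariate `z`,
  standardized to mean 0, sd 1) is spike-and-slab: `delta_i` switches the
  per-SNP regression on or off, `beta_i` has a uniform prior on
  (−0.3, 0.3), and the shared inclusion probability *P* has a Beta(1, 1)
  prior. Integrating over *P* is what makes the scan self-adjusting for
  multiple testing.

## Sampler

Metropolis-within-Gibbs, one sweep updating:

* `x` by a ±1 random walk with table-lookup log ratios (the read
  likelihood keeps `x` within a few units of its mode), refreshed every
  tenth sweep by an independence draw from Binomial(n, alpha) which
  reseeds weakly informed cells (e.g. zero coverage);
* `alpha` population by population, proposing from the conditional
  Gaussian prior given the other populations so that the Metropolis
  ratio reduces to the pool-binomial likelihood ratio;
* `pi` by a reflected random walk on [maf, 1 − maf]; proposal widths are
  tuned per SNP during pilot runs to a 25–45% acceptance window;
* `delta` by Gibbs with `beta` integrated out in closed form (Gaussian
  integral times a truncation correction for the bounded prior), and
  `beta`, where included, from its exact truncated-normal conditional —
  conjugate steps that need no tuning;
* `P` by its conjugate Beta update;
* `Omega` (core model only) by the conjugate inverse-Wishart update on
  the standardized residuals, prior IW(I, J + 2). The posterior mean over
  retained draws is the reported estimate.

Default chain lengths follow the conventions of established Pool-Seq GEA
software: 15 pilot runs of 500 sweeps, 2,500 burn-in, 1,000 retained
samples thinned by 20. All simulation studies and tests in this package
use the documented desk-scale settings (`MCMCSettings.quick()`: 4×100
pilot, 400 burn-in, 400 retained thinned by 2; the power study uses
3×80 / 300 / 400×1), which we chose as the smallest chains whose
acceptance checks are stable on one CPU.

### Initialization of Omega

The likelihood confounds each SNP's `pi_i` with the shared drift
component along the all-ones direction: a chain started at Omega = I
settles into a quasi-stable state in which `pi_i` absorbs the shared
component and the ones-direction variance of Omega never grows. The
sampler therefore starts from a method-of-moments estimate that
identifies the ones-direction variance through the *known* Beta prior
variance of `pi`: structure orthogonal to 1 from row-mean-centered
standardized frequencies (binomial sampling noise subtracted from the
diagonal), the ones-direction from the excess variance of SNP row means,
cross terms from their covariance. Eigenvalues are floored at 0.02 to
keep the start positive definite. This affects the starting point only;
the posterior updates are unchanged.

## XtX and its calibration

XtX is the variance of the Omega-standardized population frequencies,
`abar_i = (alpha_i − pi_i) / sqrt(pi_i (1 − pi_i))`, reported as the
posterior mean of the quadratic form `abar' Omega^{-1} abar` (the
per-SNP second-moment matrix is retained, so XtX can be recomputed under
any Omega). Its neutral expectation is J, and the whitening makes the
scan robust to arbitrary structure.

The posterior *mean* is deliberately under-dispersed relative to the
chi-square(J) reference — averaging over posterior uncertainty shrinks
both tails (measured Kolmogorov–Smirnov distance ≈ 0.23 at J = 16
despite a mean within 0.1% of J). This is a property of any posterior-
mean estimator, and is why practitioners calibrate XtX thresholds with
pseudo-observed data rather than against chi-square directly. For
distributional calibration the sampler also reports a *single posterior
draw* of the quadratic form (`xtx_single_draw`), which is marginally
chi-square(J) when the model is calibrated; tests bound its KS distance
by 0.05 (pure sampling noise contributes ~0.014 at 10,000 SNPs).

## Bayes factors

The support for association is the posterior-odds/prior-odds ratio
computed from the posterior inclusion probability (PIP) and the
posterior mean of *P*, reported in deciban (10·log10 BF). PIPs estimated
from S retained draws are clamped to [1/(2S), 1 − 1/(2S)] so the scale
stays finite; the maximum reportable value is recorded in the result.
This Monte-Carlo construction has the right units and ordering; it is
not the importance-sampling estimator some software also reports.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical design of a micro-geographic
GEA study: Beta(2.78, 0.710) across-population frequencies with a 0.01
maf floor, Omega-structured Gaussian population frequencies clipped to
[0, 1] (clipping is counted and warned about, not rejected — rejection
would distort the frequency distribution the model assumes), binomial
pool sampling at haploid pool size 32 (≈16 diploid plants), binomial
read sampling at a constant 25× coverage (an empirical coverage vector
can be resampled per cell instead), and a configurable fraction of SNPs
whose mean frequency shifts with a standardized covariate at coefficient
0.1 on the natural frequency scale.

Omega specifications: `identity`, compound symmetry, block-diagonal
compound symmetry, any user matrix, and a `spiked` form
`a I + b u u'` (u a smooth unit gradient, trace normalized to J) whose
single dominant axis mimics the strongly structured covariances real
regional data produce, where one principal axis can carry >90% of the
genomic variance. Compound symmetry cannot play that role in covariate
simulations because its leading eigenvector is the constant vector, and
a Spearman correlation with a constant is undefined.

Covariates with a target Spearman correlation to the leading Omega axis
are built by mixing that eigenvector with Gaussian noise and bisecting
the mixing weight until the achieved rank correlation is within a
tolerance (default 0.02) of the target, redrawing the noise when a draw
cannot reach it. Rank correlations over J populations live on a grid
with spacing 12/(J^3 - J), so for very small J the effective tolerance
is widened to that spacing (at J = 6 the nearest achievable value to
zero is ~0.03).

One subtlety of the clipped generator matters for moment checks: for
`pi` near fixation, clipping shifts the conditional mean of the observed
frequency below `pi`, and that *shared* shift masquerades as positive
cross-population correlation (~0.026 at the defaults) even though the
populations are conditionally independent. Independence diagnostics in
this package therefore remove the binned conditional mean given `pi`
before correlating; the adjusted off-diagonals are below 0.01 at
100,000 SNPs.

Not emulated: linkage disequilibrium between SNPs (SNPs are independent,
as in the power design this mirrors), spatially explicit demography,
reference bias, and mapping artifacts beyond what the filter cascade's
coverage rules model. Passing tests therefore demonstrate correctness of
the machinery under its own assumptions, not performance on real data —
with the exception of the circular-permutation null, whose entire point
is robustness to the autocorrelation the simulator does not generate
(it is tested on explicitly clustered fixtures instead).

## Filter cascade

Five ordered steps; a SNP is removed at the first step it fails, and the
statistics of each step are recomputed on the survivors of the previous
ones: (1) zero coverage in ≥ 8 populations (optionally rescaled as the
fraction 8/168 for other design sizes); (2) mean relative coverage
(coverage over the population's median coverage) above 1.5 — collapsed
paralogs; (3) frequency standard deviation below 0.004 over covered
populations, n−1 denominator — quasi-constant sites; (4) mean relative
coverage below 0.5 — regions absent from most sampled genomes;
(5) monomorphic (pooled frequency exactly 0 or 1 from read counts) in
more than 90% of covered populations, strict inequality — rare alleles.
"Allele frequency" is always the reference-allele frequency; zero
coverage is missing data, not frequency zero.

## Enrichment and the circular-permutation null

Fold enrichment compares a category's share of a selected tail (the
floor(0.005·N) largest Bayes factors, ties broken by genome order) with
its genome-wide share. Significance comes from rotating the
tail-membership indicator along the concatenated genome (chromosomes in
declared order) by a uniform random offset, recomputing FE at each of
10,000 rotations, and applying the add-one estimator
p = (1 + #{FE_null ≥ FE_obs}) / (1 + n_perm), mirrored for
under-representation. Rotation preserves runs of neighbouring SNPs —
exactly the linkage structure that makes independent shuffling
anti-conservative. Offsets are drawn with replacement; exhaustive
enumeration of all N−1 offsets is available and is what the tests
compare against on small instances. Benjamini–Hochberg correction is
applied across whatever family of tests the caller assembles (typically
all categories × covariates of one analysis).

The null-calibration check uses a 10% tail on 2,000 SNPs rather than the
0.5% analysis tail: with a handful of tail SNPs the rotation-null FE is
so discrete that no implementation can produce approximately uniform
p-values, whereas the wider tail gives the granularity uniformity needs.

## Candidate regions

Per covariate, the 50 highest-BF SNPs (genome-order tie-break) are
grouped into maximal runs with successive gaps strictly below 10 kb; runs
of at least 3 SNPs become regions spanning [min pos, max pos], with
length reported as end − start in bp. Regions from different covariates
that overlap by any base pair merge into one record listing all
supporting covariates. Genes overlap a region iff their 1-based
inclusive spans intersect; a gene starting one base past the region end
does not.

## Spatial and climate machinery

* Covariate pruning is greedy in a user-supplied preference order
  (standing in for expert ecological judgement; default input order): a
  variable is kept iff its |Spearman rho| with every kept variable stays
  ≤ 0.8.
* Climate PCA standardizes variables and reports scores, loadings and
  explained fractions; range fractions compare a subgroup's score extent
  with a reference group's on a chosen component.
* PCNM follows the classical construction: Euclidean distances,
  truncation at the longest minimum-spanning-tree edge, replacement of
  larger distances by 4× the threshold, Gower-centered principal
  coordinates, positive-eigenvalue components only. The implementation
  reproduces R vegan's `pcnm()` eigenvalues and vectors on shared
  fixtures. One consequence worth knowing: on a transect the leading
  component is the broadest spatial wave but is not strictly monotone
  (the 4t replacement bends the ends); the component order still tracks
  grain, measured as the number of sign changes. Coordinates are planar;
  project first when the extent makes Earth curvature matter.
* Spatial-grain regression fits each climate variable on all PCNM
  components jointly by OLS and applies BH-FDR at 5% across components;
  the genomic geography regression fits a principal-component score on
  latitude + longitude + latitude×longitude and reports the adjusted R².

## Power study

For each Spearman level rho and replicate: simulate a covariate at that
correlation with the leading Omega axis, simulate a dataset with planted
effects, scan under the AUX model **with the generating Omega** (the
estimation error of Omega is a separate question from the confounding
the study isolates), pool replicate Bayes factors per rho, and sweep
thresholds. ROC AUC uses the trapezoid rule on the tie-grouped sweep
(provably equal to the Mann–Whitney normalization); PR AUC integrates
precision (1 − FDR) against recall on the same grid, anchored at the
highest-threshold precision. Replicate datasets share their Gaussian
field across rho levels (the dataset seed depends only on the
replicate), so AUC comparisons across rho are paired.

Desk-scale defaults: J = 32 populations, 2,000 SNPs, 20 associated (the
same 1% rate as the full-scale design), effect 0.1, spiked Omega with
90% of variance on the leading axis, 5 replicates per rho. Under these
conditions ROC AUC falls from ≈0.93–0.95 at rho = 0 to ≈0.62–0.66 at
rho = 0.9 — the qualitative erosion of detection power by
structure-aligned covariates, at desk scale.

## Degenerate inputs and tie rules

Constant covariates cannot be standardized (error). Tails and argmax
selections break ties by genome order. FDR of an empty call set is
reported as 0 and flagged by the caller. FE with an empty category or
tail is NaN with an `undefined` flag. The upper tail is floor(f·N)
SNPs. All randomness flows from explicit seeds; identical seeds and
configurations reproduce results bit for bit, including the end-to-end
pipeline's artifact checksums.

## Known limitations

* The Monte-Carlo Bayes factor saturates at a cap set by the number of
  retained draws; ranking above the cap is arbitrary.
* Omega estimation assumes the Beta shape parameters of `pi` are known;
  they are fixed, not sampled, by default (sampling them is not
  implemented).
* The sampler is single-chain; the effective-sample-size check on the
  mean-`pi` trace warns rather than fails.
* Desk-scale chains trade Monte-Carlo precision for runtime; per-SNP
  Bayes factors at these settings carry a few dB of sampling noise.
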