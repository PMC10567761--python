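# Methods

## The estimation problem

Reference intervals (RIs) — the central 95% range of an analyte in a healthy
population — are conventionally established by sampling vetted healthy
volunteers (the *direct* method, requiring at least 120 persons per
population segment and analyte). `labri` implements the *indirect*
alternative: estimate the healthy distribution from unlabeled routine lab
results, in which healthy and pathological readings are mixed.

The model assumption is that within one gender/age segment the healthy
subpopulation's values are (multi)normally distributed — organ function under
normal wear produces tightly clustered values, with residual variation from
body size, genetics and sampling conditions — while pathological results form
a wider, upward-shifted overlay. Each segment's value distribution is
therefore decomposed as a two-component Gaussian mixture

    p(x) = a1 · N(x | mu1, Sigma1) + a2 · N(x | mu2, Sigma2),

the *principal* (healthy) component is selected, and

* the 1D reference interval is its central-coverage quantile pair
  mu ± z·sigma (z = 1.95996 at the default 95% coverage, i.e. the 2.5th and
  97.5th percentiles);
* the weight of the non-principal mass estimates the pathological fraction
  of the segment;
* in 2D the analogue of the interval is the highest-density ellipse
  {x : (x−mu)ᵀ Sigma⁻¹ (x−mu) ≤ r²} with r² = chi²₂(mass) = −2·ln(1−mass),
  computed in closed form (exactly equivalent to integrating the density
  from the mean outwards, which the test suite cross-checks numerically);
* the continuous abnormal flag of a reading x is its highest-density-region
  percentile P(f(X) ≥ f(x)) = chi²_d CDF of the squared Mahalanobis
  distance — 0 at the population center, 0.95 exactly at the RI limit (1D)
  or the 95% ellipse (2D).

Age trends of the limits are summarized by ordinary least squares: a linear
fit over the adult regime (default windows 20–60 years for creatinine,
20–50 for urea) and a cubic fit capturing the accelerating deterioration
after 60. The relative annual drift of the high limit,
`100·slope / value(ref_age)` anchored at ref_age = 20, expresses the loss of
renal clearance in %/year; the anchor convention is configurable, and with
the published adult male urea coefficients it evaluates to 0.674 %/yr.

## Fitting

Two fitters share one output contract (weights, means, covariances,
diagnostics):

* **EM (canonical).** Maximum-likelihood EM with log-space responsibilities,
  covariance ridge `reg` (default 1e-6 × mean per-dimension sample variance)
  added every M-step, and `n_init = 5` restarts — the first from a
  deterministic quantile split (1D) or seeded k-means++ (2D), the rest
  random; best final log-likelihood wins. Convergence is declared when the
  mean per-point log-likelihood changes by less than `tol = 1e-6`. The
  tolerance is deliberately tight: on strongly overlapping components
  (pathological tails shifted only ~3 SD) the likelihood surface is flat and
  looser tolerances leave the tail weight 1–2 percentage points away from
  the converged optimum. The per-iteration log-likelihood trace is retained
  and is non-decreasing by construction.
* **Variational Bayes** (`method="variational"`). Dirichlet weight prior
  with concentration 1/K and normal-Wishart component priors centered on the
  data moments (mean prior at the sample mean, unit precision scale, d
  degrees of freedom, expected precision = inverse sample covariance).
  Superfluous components are driven toward zero weight. Convergence is
  monitored on the variational objective surrogate (mean responsibility
  log-normalizer) rather than the data likelihood, which plateaus before
  shrinkage completes. Reported parameters are the posterior expectations,
  with Sigma_k the inverse of the posterior-expected precision.

**Principal selection** defaults to the largest weight, ties broken toward
the smaller generalized variance det(Sigma); selecting the component nearest
the sample median is available as an alternative rule.

**Overlap merging.** A two-component fit of a segment with essentially *no*
pathological mass is unidentifiable: the fitter splits the healthy mode into
two overlapping pieces, and the heavier piece alone under-covers the healthy
population (on a pure Gaussian sample the heavier piece typically carries
~89% of the mass and its interval is visibly too narrow). The pipeline
therefore treats a secondary component as a genuine pathological tail only
when it is clearly shifted (mean further than 2 Mahalanobis-SD from the
principal mean) or clearly widened (generalized SD ratio > 1.5); otherwise
it is re-absorbed into the healthy Gaussian by moment matching. The rule is
inert for real tails (the generator places them 3 SD away at 2.5× the
width), is configurable (`RIConfig.merge_overlapping`), and is not applied
in the acceptance-script computations, which follow their literal
fit-then-select definitions.

## Uncertainty

RI estimation error is quantified by bootstrap: B = 100 resamples of
⌊n/2⌋ values drawn with replacement, a full re-estimate per resample, and
the per-limit mean and standard deviation across resamples. Replicates whose
fit fails are dropped and counted; more than 20% failures aborts. Trend
coefficients carry standard OLS t-test p-values.

## The synthetic cohort

The data this pipeline targets are licensed clinical archives that cannot be
redistributed, so the package bundles a generator encoding the documented
statistical structure of routine creatinine/urea results:

| feature | default | unit / form |
|---|---|---|
| healthy high-limit trend, creat (m / f) | 0.00387·age + 1.108239 / 0.00298·age + 0.83276 | mg/dl |
| healthy high-limit trend, urea (m / f) | 0.13385·age + 17.18661 / 0.10959·age + 14.8156 | mg/dl |
| old-age acceleration (creat / urea) | 1e-5 / 2e-4 × (age−60)³ above 60 | mg/dl |
| stable low limits, creat (m / f) | 0.55 / 0.45 | mg/dl |
| stable low limits, urea (m / f) | 7.0 / 6.0 | mg/dl |
| pathological weight ramp | 1% at 20 → 11% (creat) / 16% (urea) at 90, linear | — |
| pathological component | healthy mean + 3 SD, SD × 2.5 | — |
| joint healthy correlation rho | 0.5 | — |
| visits per person | geometric, p = 0.3125 (median 2, mean 3.2) | — |
| implausible entries | rate 0.001, value × 100 | — |
| segment size | 10,000 results per analyte | — |

The healthy mean and SD per segment follow from the band: mean is the
center of (low, high), SD is the half-width divided by 1.95996. Because the
creatinine and urea ramps differ, per-visit pathology labels are
hierarchical — a visit is "sick" with the larger of the two weights and each
analyte is pathological with conditional probability w_a/w_max — so every
analyte's marginal pathological fraction matches its ramp exactly while
abnormality remains correlated across the panel.

What the generator does *not* emulate: real-world age pyramids (ages are
uniform over 20–90), longitudinal disease progression within a person,
non-Gaussian healthy skew, laboratory batch effects, and unit heterogeneity.
Passing the recovery suites therefore demonstrates correctness of the
estimation machinery under the stated mixture model, not performance on real
archives. One deliberate artifact: pathological draws are raw Gaussians, so
in extreme-age urea segments a fraction of a percent of them fall below
zero. They are removed by the plausibility filter like any other impossible
reading; generating them (rather than truncating the component) keeps every
segment an exact two-Gaussian mixture, which is what makes the generator
usable as a parameter-recovery oracle.

## Numerical and interface choices

* Plausibility filtering retains `0 < value ≤ threshold` (thresholds 25
  mg/dl creatinine, 150 mg/dl urea; boundary inclusive). For
  recovery-oracle measurements the upper threshold alone is applied, since
  removing the (physically impossible, but model-exact) negative tail of
  the synthetic pathological component measurably attenuates the recovered
  weight.
* Duplicate (person, date, analyte) rows keep the first occurrence by file
  order; all results (not one per person) enter estimation.
* Segments with fewer than 120 values are flagged unreliable and excluded
  from estimation; the population model stores them as explicit gaps and
  `predict` raises on missing segments rather than extrapolating across
  ages.
* Per-segment fit seeds derive deterministically from the run seed and the
  segment labels (SeedSequence), so tables and models are reproducible
  regardless of iteration order.
* Near-singular joint covariances (|rho| > 0.999) are rejected rather than
  silently inflated. Chord intervals solve the ellipse-slice quadratic in
  closed form; an empty chord is a valid result meaning the fixed reading
  alone is outside the joint region. The alternative conditional-Gaussian
  interval (never empty) is exposed separately as `conditional_interval`.
* Degenerate trend series (zero variance) report R² = 0 with a warning
  rather than NaN.

## Problem sizes used in the checks

The end-to-end acceptance check runs the full default cohort — 71 ages × 2
genders × 10,000 results per analyte per segment (~2.8M rows) — through
`ri_table` and `build_population_model` (~4.5 minutes on one CPU) and
verifies that every segment's limits land within 0.15 healthy-SD of the
generating curves (median within 0.05 SD) and that the pathological-weight
ramp endpoints are recovered within ±0.02. Unit and property tests use a
compact cohort (3 ages, 600 results per segment) and seeded simulations of
2,000–20,000 points; Monte-Carlo oracles use 10⁶ draws.

## Known limitations

* The ML tail weight of heavily overlapping mixtures has ~1pp sampling
  spread at n = 10,000 even at the converged optimum; per-segment
  pathological fractions should be read with that uncertainty.
* K is fixed at 2 by default; segments containing several distinct
  pathological modes are summarized by a single tail component. No
  model-order selection is performed.
* Ages are exact-match keys in the population model; no smoothing or
  interpolation between adjacent ages.
* The percentile flag is calibrated under the fitted Gaussian; departures
  from normality in the true healthy distribution translate directly into
  flag miscalibration.
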