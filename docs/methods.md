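# Methods

`affsync` quantifies *affective synchrony* — the co-fluctuation of a user's
expressed sentiment with that of the peers they interact with — and models
long-run *sentiment trajectories* in online health-community comment
histories. This note records the model, its assumptions, the defaults, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## The analysis pipeline

1. **Ingestion and eligibility.** Interactions arrive as JSON-Lines records
   pairing each user comment with the parent text it replied to. Comments
   flagged as removed (or matching deletion sentinels such as `[removed]`),
   comments with missing text, and comments with fewer than 3 words after
   URL/emoji stripping are excluded, each with exactly one reason code.
   Users need at least 100 post-exclusion interactions to be analyzed; the
   floor exists because wavelet estimates at the lowest frequencies are
   unreliable on short series. The eligibility threshold and the minimum
   series length are separate parameters that default to the same value.

2. **Sentiment scoring.** Two pluggable lexicon scorers are applied to every
   retained text. Scorer A is a rule-based valence scorer: matched token
   valences are summed, a negator within the preceding three tokens flips
   and damps a valence by a factor of −0.74, booster tokens add ±0.293-type
   increments toward the token's sign, and the total is compressed into
   [−1, 1] by `t/sqrt(t² + 15)`. Scorer B is a positive/negative word-list
   tone score, `100·(pos − neg)/(pos + neg + 1)` in [−100, 100]. The
   *compound* score is the mean of the two z-scored outputs, standardized
   over **all** retained texts of all analyzed users (comments and parent
   posts pooled) so that per-user trajectories share one scale. Agreement
   between the scorers is reported as Pearson r and two-item Cronbach α
   (equal to 2r/(1+r) for standardized items). The bundled word lists are
   compact open lists written for this package; any two-column
   token/valence file can replace them, and scorer B claims no equivalence
   with proprietary dictionaries.

3. **Wavelet synchrony.** Each user contributes a paired series (own
   sentiment, peer sentiment) indexed by interaction number (dt = 1
   interaction, not clock time). Both series are passed through an
   empirical-CDF (percentile) transform — average ranks for ties — to tame
   spikes, then through a Morlet CWT (ω₀ = 6) on a dyadic scale ladder
   s₀ = 2, dj = 1/12, with the largest Fourier period at least n/2. The FFT
   path zero-pads to the next power of two; the cone of influence uses the
   √2·s e-folding time, and all summary statistics exclude points outside
   it. The Morlet daughter is evaluated as the full frequency-domain
   Gaussian rather than the Heaviside-truncated analytic form; at ω₀ = 6
   the two differ by ~e⁻¹⁸, and the full Gaussian is an exact Fourier pair
   with the time-domain Morlet, which is what the test suite's convolution
   oracle exploits.

   - **XWT significance**: |W^XY| is tested pointwise against the product
     of the two theoretical AR(1) red-noise spectra (lag-1 coefficients
     estimated from each percentile-transformed series, clipped to ±0.99)
     using the critical value z solving 2z·K₁(2z) = α — the
     sqrt-product-of-χ² null (z ≈ 2.0 at α = 0.05).
   - **WTC**: coherence is the smoothed normalized cross-spectrum,
     R² = |S(W^XY/s)|² / (S(|W^X|²/s)·S(|W^Y|²/s)), with S a Gaussian of
     SD equal to the scale in time and a 0.6-octave boxcar across scale
     (the standard Morlet decorrelation width). Its null distribution is
     simulated: independent AR(1) pairs with the fitted coefficients, with
     the per-scale (1−α) quantile of coherence pooled over time as the
     critical value. The production default is 2000 simulations; the test suite and
     the acceptance script use 200, which changes critical values by less
     than the Monte Carlo standard error.

   Per-user summaries: the fraction of reliable points with significant
   common power, the same for coherence, and the unweighted circular mean
   of the relative-phase angle over significant common-power points
   (0° in-phase, 180° antiphase; positive = the user leads). Fractions are
   stored in [0, 1]; any percentage display is a presentation choice. Band
   summaries restrict the period rows to low [20, 32] (closed endpoints),
   medium [10, 20), and high (0, 10) interactions.

4. **Shuffled baseline and group tests.** The identical pipeline is re-run
   on a permutation of each user's own series with the peer series left in
   order (`shuffle-self`, the default: alignment is destroyed, both
   marginal distributions preserved; `shuffle-both` is available). Paired
   two-tailed t tests compare real against shuffled cohorts; both Cohen's d
   conventions are reported (d_av over the averaged condition SDs, d_z over
   the SD of differences) because paired-design effect sizes are not
   uniquely defined. Band comparisons use a one-way repeated-measures
   ANOVA with the conventional within-subject error term, df₂ =
   (n−1)(k−1); this convention is stated in the report metadata since
   other error-df choices circulate in applied work. Construct validity is
   summarized by the pairwise correlation table of per-user Pearson r
   against real and shuffled wavelet metrics (listwise deletion).

5. **Trajectories.** Each user's sentiment series is collapsed into 100
   proportional windows (window 1 = first 1% of their activity); when the
   length is not divisible by 100 the earliest windows absorb the
   remainder, which keeps the transform deterministic and
   order-preserving, and the size-weighted mean of window means equals the
   series mean exactly. The growth model is a linear mixed-effects
   regression (REML, statsmodels MixedLM) of window sentiment on the
   window index with a per-user random intercept; common power, days
   active, mean word count and mean health-word percentage enter as
   covariates, with the window × common-power × days-active interaction
   structure. All continuous variables, response included, are z-scored
   across the table, so coefficients are standardized β's and are invariant
   to affine rescaling of the raw predictors. Variance components are
   summarized as ICC = τ₀₀/(τ₀₀+σ²) and marginal/conditional R² in the
   variance-partition sense (fixed; fixed+random over total). "Days
   active" is computed both as the span (last − first post) and as the
   count of distinct active days; the span is the default regressor.
   The `interaction_surface` helper evaluates the model-implied
   window slope over a ±1 SD moderator grid and flags grid points beyond
   ±2 SD as extrapolation.

## The synthetic community generator

Real corpora of this kind are withheld for privacy, so every stage is
exercised on generated communities with known ground truth. Per user:

    peer(t) = AR1(φ) + sin(2πt/P + φ₀)
    self(t) = c·sin(2πt/P + φ₀ + λ) + (1−c)·AR1'(φ) + β·t/(n−1) + ε

with unit-variance AR(1) components, white noise ε ~ N(0, σ²), coupling
c ∈ [0, 1], phase lead λ applied only to the oscillatory component (so the
relative-phase ground truth is exact), and a linear tenure trend β over the
normalized interaction index. Defaults: history lengths uniform in
100–600 interactions (bracketing a few hundred comments per user above the
eligibility floor), oscillation period 24 (inside the low band, where
community-level synchrony is expected to concentrate), φ = 0.3 (moderate
autocorrelation, as seen in affect series), σ = 0.5, coupling 0.4, tenures
10–500 days. Per-user seeds derive deterministically from the master seed
(SeedSequence of (seed, user index)), so identical configs are
byte-identical after serialization, including under partial regeneration.

The peer stream is a single exogenous process per user, although real
"peers" are many distinct authors — the analysis treats peer sentiment as
one interleaved series, so one generating process suffices. Optional
token-level text is generated from the bundled lexica with the
positive-draw probability rising linearly in valence, which makes the
text→score→series path testable end to end but does not emulate grammar,
sarcasm, topic drift, reply-tree structure or multi-community activity.
Passing tests therefore demonstrate correctness of the *computational
pipeline* under known coupling/trend/noise conditions, not robustness to
every property of real social-media language.

The windowed-cohort generator used for growth-model recovery studies
produces window-mean panels directly with residual variance 0.88 and
random-intercept variance 0.07 — magnitudes typical of windowed sentiment
panels — so CI coverage and sign-recovery claims are evaluated at realistic
signal-to-noise.

## Numerical choices and degenerate inputs

- Percentile transform: average ranks for ties (deterministic,
  permutation-safe); non-finite inputs rejected.
- FFT zero-padding to the next power of two; coefficients truncated back.
- AR(1) estimates clipped to ±0.99 (a linear ramp estimates near 1).
- Zero-variance inputs (constant series, constant predictors) raise
  errors rather than producing NaNs silently.
- Coherence is clipped to [0, 1]; points with zero smoothed denominator
  are set to 0.
- The WTC Monte Carlo threshold pools coherence values over simulations
  and time at each scale; it is deterministic in its seed.
- Mixed-model fits use statsmodels' default BFGS-based REML path; the
  L-BFGS option was observed to collapse the random-intercept variance to
  zero on profiled boundaries and is not used.

## Problem sizes

Test-suite and acceptance-script runs use desk-scale sizes chosen to keep
Monte Carlo error small relative to the assertions made: 200-seed null
calibrations, 200 replicate cohorts for type-I error, 20 cohorts of 50
users for power, 200 replicate mixed-model fits at 199 users × 100 windows,
and 200-draw coherence nulls. The pipeline exposes production-scale
settings (2000-draw nulls, arbitrary community sizes) through its config.

## Known limitations

- Pointwise wavelet significance is used; no area-wise (cluster)
  correction is applied, so significant-point fractions are comparative
  statistics, not corrected hypothesis tests per user.
- The AR(1) red-noise null is fitted marginally per series; strongly
  non-AR(1) backgrounds (long memory, regime switches) would miscalibrate
  pointwise rates.
- Relative-phase means are unweighted over significant points; weighting
  by cross-power is a plausible alternative not implemented.
- No random slopes or autocorrelated residuals in the growth model; the
  window effect is linear by design.
- The bundled lexica are compact; production analyses should supply
  domain-validated word lists via the lexicon file interface.
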