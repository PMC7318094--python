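# Methods

`neofba` estimates a functional brain age (FBA) from multichannel
preterm neonatal EEG and evaluates the predicted age difference
(PAD = FBA − PMA, where PMA is postmenstrual age in weeks) as a
maturational biomarker. This note documents the model, the numerical
choices, the synthetic cohort used for validation, and what the tests
do and do not demonstrate.

## Signal model and preprocessing

The preterm EEG is discontinuous: high-amplitude bursts separated by
quiescent interburst intervals (IBIs), with both the IBI distribution
and the temporal shape of bursts changing rapidly with maturation.
All analysis operates on bipolar derivations formed from referential
recordings; derivation order is fixed by the montage preset, never by
the file. Three montages ship with the package: the 8-derivation
neonatal double banana (`vienna_double_banana`), a 2-channel
fronto-parietal aEEG-monitor layout (`utrecht_2ch`), and a 2-channel
fronto-central layout (`frontocentral_2ch`) for transferring a model
onto 2-channel recordings.

Signals are band-limited with a causal Butterworth cascade: 4th-order
high-pass at 0.5 Hz, then 6th-order low-pass at 16 Hz. Forward-only
filtering is deliberate — the intended deployment is real-time cot-side
trending, and none of the features depend on phase alignment, so the
group delay is irrelevant. Recordings are cut into fixed-length epochs
(default 1 h with 75 % overlap; only fully contained epochs are
emitted) and each epoch passes three artifact rules:

1. **spatial imbalance** — reject if the ratio of the largest to the
   smallest per-derivation mean absolute amplitude exceeds 2 (strictly;
   a ratio of exactly 2 is kept);
2. **excessive amplitude** — reject if more than 25 % of envelope
   samples exceed 500 µV;
3. **low amplitude** — reject if more than 50 % of envelope samples
   fall below 5 µV.

All three rules are always evaluated, so rejection reasons accumulate.
Rules 2–3 read the same smoothed analytic-signal envelope as burst
detection, keeping "burst amplitude" and "EEG activity" internally
consistent. "Mean amplitude" in rule 1 is the mean of |x(t)| (not RMS).

## Burst analysis

The amplitude envelope is the magnitude of the Hilbert analytic signal
smoothed by a 0.39 s (100 samples at 256 Hz) moving average — long
enough to suppress carrier ripple, short enough to preserve burst
structure at the 0.5 s scale. Bursts are maximal supra-threshold runs
of this envelope; sub-threshold gaps shorter than `merge_gap_s`
(default 0.2 s) are bridged, and merged runs shorter than `min_burst_s`
(default 0.5 s) are discarded.

The default detection threshold is **15 µV**. The discontinuous preterm
EEG this pipeline targets carries continuous interburst background
activity of roughly 7–9 µV — which is also why ordinary recordings
survive artifact rule 3 — so the threshold must sit above that
background and below typical burst peaks (tens of µV). All detection
parameters are exposed in the API and can be adapted to recordings with
a different noise regime.

The **average burst shape** is the duration- and peak-normalized mean
envelope profile: each burst is resampled to L = 100 points on
u ∈ [0, 1], scaled to unit peak, averaged pointwise, and renormalized.
Its **asymmetry**

A = ∫₀¹ s̄(u)(2u − 1) du / ∫₀¹ s̄(u) du

is a normalized first moment about the burst midpoint: exactly zero for
time-symmetric shapes, negative when amplitude mass concentrates early
(fast rise, slow decay), bounded in (−1, 1), and parameter-free. The
moment integral is evaluated exactly for the piecewise-linear
interpolant of the sampled shape (per-interval Simpson with
interpolated midpoints — the integrand is quadratic per interval, so
there is no quadrature error); a decaying ramp s̄(u) = 1 − u gives
A = −1/3 to machine precision. **Sharpness** is the negative second
difference of the shape at its peak per unit u²; a flat-topped shape is
evaluated mid-plateau (sharpness 0), not at the plateau edge.

The `burst.*` family (40 features) covers: asymmetry and sharpness
overall and within four dyadic duration classes (0.5–1, 1–2, 2–4,
4–8 s); means and SDs of log₁₀ duration/area/peak; burst rate and
fraction of time in burst; power-law slopes of the duration and area
distributions (ordinary least squares on the log–log complementary
empirical distribution over the central 90 % of the support — OLS
rather than MLE to keep the estimator deterministic and
dependency-free); the area-versus-duration scaling exponent; IBI
median/IQR/95th percentile and further size and interval percentiles.
Features are computed per derivation and aggregated by the median
across derivations (robust to one noisy derivation); features that
cannot be estimated (e.g. an empty duration class) are left missing and
imputed with training medians at model time — never with zero, which is
a meaningful asymmetry value.

## Phenomenological and advanced features

The `phenom.*` family (46 features) mirrors visual EEG review: Welch
band powers (8 s Hann segments, 50 % overlap; bands 0.5–3 / 3–8 /
8–15 Hz — the standard neonatal delta/theta/alpha-beta split, exposed
in the API), spectral edge frequencies (75/90/95 %), band ratios,
envelope moments and percentiles, range-EEG (2 s peak-to-peak windows)
percentiles and asymmetry, IBI statistics, discontinuity and
suppression measures.

The `adv.*` family (10 features): suppression curve (fraction of time
the envelope stays below each threshold of a log-spaced 1–100 µV grid;
summarised by its mean and the 50 % crossing point), multiscale sample
entropy (m = 2, r = 0.2·SD, scales 1–10; summarised by mean and slope
versus log scale), median phase lag index in 0.5–8 Hz (sign(0) = 0, so
zero-lag coupling scores zero), an activation synchrony index (median
pairwise correlation of 2 s-windowed log-envelopes), characteristic
path length of the thresholded coherence graph (edge weight
1/coherence, threshold 0.2, harmonic-mean convention for disconnected
pairs), spectral entropy, Higuchi fractal dimension, and line length.
The last three fill the family to its ten slots with standard
complexity measures; the registry documents every formula and the set
is swappable. For tractability, sample entropy runs on the signal
decimated to 32 Hz with at most 1000 samples per coarse-grained scale,
and the Higuchi estimate uses the first 20 000 samples; both choices
trade a little estimator variance for whole-cohort runtimes.

## Age model

An ε-support-vector regression with Gaussian kernel
K(x, x′) = exp(−‖x − x′‖²/σ²) predicts PMA from the standardized
features, with a fixed recipe instead of a hyperparameter search:
kernel scale σ = 10, box constraint C = IQR(training PMA)/1.349 (the
IQR-to-SD conversion for a normal), ε = C/10. Standardization
(training mean/SD) precedes the kernel — a fixed kernel scale is
meaningless on raw heterogeneous units. Features are median-imputed
from training data only.

Evaluation is leave-one-subject-out (LOSO): all recordings of one
infant are held out per fold, so no subject contributes to both train
and test. Optional backward feature selection runs inside each training
fold: greedy single-feature removal scored by subject-grouped 4-fold CV
mean squared error, stopping at the first round with no strict
improvement, ties broken toward the lexicographically smaller name —
determinism over optimality. The per-recording FBA is the arithmetic
mean of its epochs' predictions (exactly, not approximately), and
PAD = FBA − PMA. A fitted model can be applied to an external cohort
with its stored standardization, never refit; evaluation can be
restricted to a PMA range while predictions remain available outside
it.

One capacity note: with the printed recipe the kernel is smooth and the
dual coefficients are bounded by C, so very small cohorts underfit —
the ε-tube property (most training residuals within ε) emerges reliably
only once a few hundred epochs are available.

## Statistical evaluation

* **Goodness of fit**: Pearson r with a 95 % percentile bootstrap CI,
  bias (mean error), error variance, median absolute error with IQR,
  and the percentage of recordings within ±1 and ±2 weeks (boundaries
  inclusive). "Variance" is the variance of the error FBA − PMA.
* **Model comparison**: bootstrap of Δr over recordings; significant
  when the 95 % percentile interval excludes zero. Degenerate
  resamples are redrawn and counted.
* **Equivalence (TOST)**: two one-sided Welch t-tests of the mean
  absolute-error difference against a ±0.5-week boundary; p is the
  larger one-sided p. Two identical zero-variance samples are defined
  equivalent (p = 0), since their difference is exactly zero.
* **Repeated-measures correlation**: a linear mixed model
  PMA ~ FBA with a random intercept per infant (REML); the adjusted r
  is the correlation between observed PMA and the conditional fitted
  values, with a subject-level bootstrap CI. When the between-subject
  variance collapses the adjusted r equals the ordinary r and is
  flagged. (An alternative operationalization — marginal R² — would
  ignore the subject-level information and was not used.)
* **PAD versus outcome**: infants with ≥ 3 serial recordings, grouped
  by Bayley-derived outcome (all indices > 85 normal, any < 70
  abnormal, otherwise mildly abnormal; boundary scores fall to mildly
  abnormal by the strict inequalities). One-way ANOVA with Levene's
  variance check, Tukey-corrected pairwise comparisons, per-group
  two-sided one-sample t-tests against zero, and Cohen's D with the
  Hedges small-sample correction (1 − 3/(4n − 5) one-sample; pooled-SD
  analogue two-sample). Group zero-tests use one mean PAD per infant,
  not pooled recordings. All bootstraps use percentile intervals with a
  mandatory seed.

## Synthetic cohort

No public data exist for this recording type, so the package ships a
generator that embodies the maturational structure the pipeline is
built to detect, with planted, recoverable ground truth:

* burst timing is a renewal process with lognormal IBIs
  (σ_ln = 0.6) whose median interpolates linearly from 12 s at an
  effective age of 25 weeks to 3 s at 38 weeks;
* burst durations are lognormal (median 2 s, σ_ln = 0.5); peak
  amplitudes lognormal (median 60 µV, σ_ln = 0.35) — a realistic scale
  for preterm bursts that also keeps burst tails above the detection
  threshold;
* each burst's profile is a two-sided quadratic kernel with peak
  position p, whose duration-normalized asymmetry is exactly p − ½;
  p follows a linear asymmetry-age map (−0.35 at 25 wk to −0.05 at
  38 wk), so bursts become more symmetric with maturation;
* the carrier is per-electrode independent 0.5–16 Hz Gaussian noise
  amplitude-modulated by the shared burst envelope riding on a
  continuous 7 µV interburst background plus a 2 µV amplifier floor.
  Shared burst timing gives envelope-coupling measures real structure
  while phases stay independent. The background keeps interburst
  activity above the 5 µV artifact floor, as in real discontinuous
  preterm EEG;
* infants receive gestational ages uniform in 24–28 wk, first
  recordings near 27 wk PMA and fortnightly follow-ups, and an outcome
  group (60/25/15 % normal / mildly abnormal / abnormal); abnormal
  infants mature with a 2-week lag of effective age behind PMA (mildly
  abnormal: 1 week) — exactly the PAD construct the evaluation module
  tests.

All randomness derives from one integer seed through `SeedSequence`
substreams; a cohort is bit-reproducible. Recordings can be emitted as
EDF (16-bit, ±1000 µV, 1 s records; quantization step ≈ 0.03 µV) with
a metadata sidecar CSV, or streamed in memory for large cohorts.

**What the generator does not emulate**: sleep-state cycling, focal or
asymmetric pathology, artifact morphologies beyond the Gaussian floor
(artifact fixtures are hand-constructed in tests), realistic spectral
maturation of the carrier, and inter-electrode distance effects.
Passing tests therefore demonstrate that the pipeline recovers planted
burst/IBI/asymmetry structure and planted maturational lags — not that
it attains any particular accuracy on clinical EEG.

## Reference problem sizes

The reference validation cohort is 40 infants × 3 serial recordings of
30 minutes each, analysed as three non-overlapping 10-minute epochs —
so the per-recording FBA is a genuine epoch average, as in cot-side
practice where recordings outlast the analysis window. On this cohort
the full pipeline (LOSO, no selection) reaches r ≈ 0.9 with a median
absolute error of ≈ 0.5 weeks, and planted lags separate the outcome
groups. Shorter epochs raise burst-sampling noise in the shape
features; a single 10-minute epoch per recording caps the
single-feature correlation near 0.82 on this generator.

## Known limitations

* The 96-item feature registry reconstructs the three families
  (phenomenological / burst / advanced) at their canonical counts from
  their published descriptions; it is not a verbatim copy of any
  clinical inventory.
* The suppression curve, activation synchrony index and coherence path
  length are standard operationalizations of their named constructs;
  variant definitions exist in the literature.
* Backward selection is greedy and deterministic; it makes no claim of
  finding the globally optimal subset.
* The SVR recipe is fixed by design; no hyperparameter search is
  performed, so performance on cohorts with a very different age spread
  depends on the IQR-based box constraint scaling appropriately.
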