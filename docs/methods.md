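# Methods

## The problem

`breathauth` implements a biometric system built on the fluid mechanics of
exhaled breath. A short (nominally 1.5 s, 10 kHz) hot-wire anemometer
recording of the turbulent exhaled airflow carries structure shaped by the
subject's extrathoracic airway. The package answers the two standard
biometric questions from such a recording: *confirmation* ("is this person
who they claim to be?") and *identification* ("who is this person?").

## Pipeline

1. **Segmentation.** Each trial of N samples is cut into overlapping windows
   of `floor(N/10)` samples slid by half a window: 19 segments of 1500
   samples for the nominal N = 15000, with every interior sample appearing
   in exactly two segments. Trailing samples that do not fill a window are
   dropped; padding would fabricate data.
2. **Normalization.** Each segment is z-scored with the population standard
   deviation (ddof 0), z(i) = (x(i) − μ)/σ, making all downstream features
   unitless and sensor-agnostic. By default each segment is standardized
   independently so that every feature-extraction unit is self-normalized;
   `normalize_scope="trial"` standardizes the whole record instead — the
   choice matters little because all shipped features are translation and
   scale invariant.
3. **MFDFA screening.** Multifractal detrended fluctuation analysis is run
   on every segment: the profile (cumulative sum of the mean-subtracted
   segment) is split at each scale s into `floor(N/s)` windows from both
   ends, each detrended by an order-1 polynomial (MF-DFA1); the fluctuation
   function F_q(s) aggregates the q/2-th moments of the residual variances
   (a log-average at q = 0). h(q) is the log–log regression slope of
   F_q(s); τ(q) = q·h(q) − 1; the singularity spectrum follows by Legendre
   transform with α = dτ/dq taken by central finite differences.
   Segments whose spectrum is *non-convex* — the α sequence reverses
   direction (a fold), or f(α) is not rise-then-fall along α — or whose
   width ω < 0.05 are discarded. The filter implements the observation that
   folded or nearly-monofractal spectra indicate irregular exhalation,
   non-stationarity or finite-size artifacts rather than usable structure.
4. **Features.** Each valid segment becomes a 10-vector: β (α at the
   spectrum maximum), ω (spectrum width) — the asymmetry ε is computed
   alongside them but is not among the ten classifying features — and
   eight time-domain statistics: the absolute sum of
   changes, AR(10) coefficients 3 and 4 (conditional least squares), peak
   count at support 1, Ricker-CWT ridge peak counts at max widths 1 and 5,
   the partial autocorrelation at lag 3 (Levinson–Durbin on the biased
   sample ACF), and the adjusted Fisher–Pearson excess kurtosis G2.
5. **Reduction operators.** For the larger automated candidate pools the
   package ships a reduction cascade: a low-variance filter (columns are
   min–max scaled to [0, 1] first, so the 1% threshold is meaningful across
   heterogeneous units), a pairwise |Pearson r| > 0.8 filter (first-come
   column order, deterministic), removal of absolute-scale features
   (means, extrema, quantiles — anything that keys on how hard a subject
   blows rather than on flow structure), and a prevalence vote over the
   impurity importances of all pairwise random forests (ties broken by mean
   importance rank, then name).
6. **Enrollment.** Every user's feature rows are split 60/40 into train and
   test *by whole trials* (segments of one exhalation never straddle the
   split). One seeded random-forest binary classifier (100 trees, default
   depth) is trained per unordered user pair: C(n, 2) models; adding a user
   adds exactly n models and leaves existing ones untouched.
7. **Confirmation.**
   *HT*: the claimant's test rows are tested against the training rows of
   each pair containing the claimed user with two-sample Hotelling T² tests
   (pooled covariance, exact F reference distribution) at 99.9% confidence;
   in each pair the higher p-value wins, both-rejected yields no prediction.
   *ML*: each pair model containing the claimed user votes "yes" if the
   majority of its row-level predictions equal the claimed user.
   Either way the confidence of confirmation is η = 100·v/(n−1) and the
   user is confirmed when η ≥ 50%.
8. **Identification.** The confirmation block runs for every enrolled
   identity; the per-method vote vectors (on the η scale) are fused by a
   convex combination, default V′ = 0.3·V_HT + 0.7·V_ML; the unique argmax
   of V′ is the answer provided it reaches η_t (default 55%), otherwise no
   identification. Metrics: TCR = c/n·100 for confirmation;
   precision P = t/(t+f)·100 and accuracy E = t/n·100 for identification,
   reported as μ ± 2σ over re-randomized train/test shuffles (66 by
   default).

## Numerical choices

- **q grid** −5…5 in steps of 0.25 (q = 0 via the log-average). MFDFA
  moments above |q| ≈ 5 are noisy on 1500-sample segments, so the pipeline
  stays at ±5; validation runs against the cascade oracle use ±8 because
  the spectrum *endpoints* (α_min, α_max) are truncated at finite q — at
  q ∈ [−5, 5] the analytic width of a p = 0.6 cascade is understated by
  ~23% before any estimation error.
- **Scales** 10 log-spaced integers in [16, N/4]: the lower bound avoids
  order-1 detrending artifacts, the upper bound keeps ≥ 4 windows per end.
- **Convexity tolerance 0.01** on both the α-fold and f-unimodality checks.
  Finite-difference jitter on clean segments reaches ~1e−3; genuine folds
  measured on intermittent segments are an order of magnitude larger
  (α reversals of 0.03–0.13), so 0.01 separates the two populations.
- **ε formula**: ((α_max − β) − (β − α_min))/ω — bounded in [−1, 1], zero
  for symmetric spectra, positive when the weak-singularity branch is
  longer. (No standard formula exists; this is the package's convention.)
- **CWT peak counting**: scipy ridge-line detection over integer widths
  1..w with `min_snr = 3` and a constant-input guard. With the default
  SNR of 1, single-sample noise wiggles register as peaks and the count
  saturates near the series length/30 regardless of structure; at SNR 3
  constructed fixtures (one/two isolated bumps in noise) are counted
  exactly and the statistic remains discriminative on turbulence segments.
- **Hotelling ridge**: a pooled covariance with condition number > 1e12
  gets 1e−8·trace/p added to its diagonal and the result is flagged;
  numerically failed pairs count as "no prediction", never as rejections.
- **Degenerate inputs**: constant segments are excluded at normalization;
  all-zero-variance MFDFA windows raise a degenerate error that the
  pipeline maps to a rejected segment with reason `degenerate`.
- **Determinism**: every stochastic step (splits, forests, generator)
  derives from one `numpy` SeedSequence tree; reports embed the full
  configuration, and two runs under one seed are byte-identical.

## The synthetic cohort

No public corpus of exhaled-breath turbulence exists, so the package ships
a seeded generator used by the tests and by anyone exercising the pipeline:

    signal = baseline + amplitude · envelope(t) · (1 + 0.3 · fluct) + noise

- `fluct` is a binomial multiplicative cascade (multiplier p, 2^14 nodes,
  truncated to 15000 samples), mean-removed, AR(1)-colored (coefficient
  0.3) and scaled to unit variance. The cascade is the one multifractal
  process with closed-form spectrum — τ(q) = −log2(p^q + (1−p)^q),
  ω = log2(p/(1−p)) — giving a rigorous desk-scale oracle for the MFDFA
  stage.
- `envelope(t)` is a smooth 0.3 s rise / 0.8 s plateau / 0.4 s decay,
  floored at 0.1 because acquisition is triggered by the exhalation itself
  and never records truly zero flow; values are floored at 1% of baseline,
  emulating the anemometer's positive record.
- Users differ by p, equally spaced over [0.58, 0.70]·separation around
  0.64; each trial jitters p by N(0, 0.01²) and redraws the cascade. The
  range was calibrated once so that clean profiles keep ≥ 90% of segments
  past the validity filter (above p ≈ 0.72 the 1500-sample cascade spectra
  fold intrinsically); `separation = 0` makes all users exchangeable.
- `inject_bad_segments` produces the two realistic failure modes: a regime
  switch (fluctuations smoothed around an abrupt amplitude change) and
  spike bursts, both of which trip the validity filter.

**What the generator does and does not emulate.** It reproduces the
structural properties the pipeline consumes: positive envelope-shaped
records, per-user multifractal structure with closed-form ground truth,
intra-user trial variability, and occasional invalid segments. It does not
model airway physiology, real spectral shapes of breath turbulence, sensor
drift, or realistic inter-subject feature spreads — the separation knob is
a free parameter, not calibrated to human data. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms, not
field performance on real breath recordings.

## Problem sizes used in tests

The shipped test and acceptance runs use a 5-user cohort of 10 trials each
(950 segments), 10 evaluation shuffles, cascade oracles at N = 2^12 and
2^14 over 5 seeds, and a 1000-replicate Hotelling null calibration — sizes
at which every check is stable yet the whole suite runs in minutes on one
CPU. The library-growth law is checked exactly for n up to 200 users.

## Known limitations

- One-vs-one ML confirmation has no reject option: an impostor's rows fall
  on the claimed user's side of every pair boundary that does not involve
  the impostor, so a claim to a *neighboring* identity can collect up to
  n−2 favorable votes. The genuine claim still scores strictly highest,
  which is what identification exploits; deployments needing a hard
  confirmation guarantee should weight the HT engine (which does reject
  distribution mismatches) or raise the confirmation threshold.
- Hotelling tests compare a claimant's *pooled segments* against stored
  training features; with many segments the test is powerful enough that
  benign intra-user drift can reject a genuine claim — visible as the HT
  engine's lower and noisier TCR.
- MFDFA spectrum endpoints are biased inward at finite length and finite
  |q|; ω is therefore a relative, not absolute, multifractality measure.
- The feature registry ships the ten signature features plus a small set of
  absolute-scale examples; it is extensible but intentionally not a
  reimplementation of the ~700-feature automated extraction pools.
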