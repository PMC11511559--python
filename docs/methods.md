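# Methods

`bcikit` implements a complete EEG brain–computer-interface decoding stack:
a motor-imagery (MI) classification chain, a P300 speller chain, a
finite-state controller that turns four decoded thoughts into application
actions, and generators that simulate both paradigms so the stack can be
exercised end to end without recordings. This note documents the models,
the conventions that carry numerical consequences, and the limits of what
the synthetic benchmarks demonstrate.

## Signal model and domain objects

A `Recording` is a channels × samples matrix in microvolts with a sampling
rate, 10-10/10-20 electrode labels and an event table (MI cues or speller
intensifications). Epochs are half-open windows `[start, end)` in 0-based
sample indices; an epoch contains `n = floor((t_end − t_start) · fs)`
samples beginning at the event sample. The floor rule is load-bearing: a
0–667 ms window at 240 Hz yields exactly 160 samples, which the speller
chain later reduces to 14 per channel.

Dataset cleaning removes recordings that lack required electrodes or
contain non-finite samples; survivors pass through untouched, so cleaning
is idempotent.

Montage neighbor sets drive the surface Laplacian: *small* neighbors are
the 4 nearest electrodes by Euclidean distance in normalized 2-D scalp
coordinates, *large* the 4 next-nearest. Coordinates come from the
idealized standard montage shipped with MNE, projected to the x–y plane
and scaled to the unit disc. The built-in montage covers the 21-electrode
motor strip (FC/C/CP rows); a generic builder accepts arbitrary positions.

## Spatial filtering

Common average reference subtracts the instantaneous mean across all
electrodes; the surface Laplacian subtracts the unweighted mean of each
electrode's small or large neighbor set. Both are per-sample linear maps;
CAR is a projection (idempotent) and the Laplacian annihilates common-mode
signals. Edge electrodes with fewer neighbors than nominal use whatever
neighbors remain, preserving channel count for the fixed-length feature
vectors downstream. Inverse-distance weighting is available behind a flag
but off by default — the reference operation is a plain neighbor mean. The
default chain order is CAR first, then the small Laplacian; each stage
toggles independently, and the combination (rather than either alone) is a
package choice, not a constraint of the method.

## The MI feature bank

Seventeen features are computed per channel and concatenated channel-major
(62 channels → 1054 values). Conventions that matter:

* **Band power** — Welch PSD (Hann window, 1 s segments, 50 % overlap,
  mean averaging, one-sided density) integrated trapezoidally over the
  µ (8–12 Hz) and β (13–30 Hz) bands. Event-related desynchronization
  lives here: imagined movement suppresses µ/β power over contralateral
  sensorimotor cortex.
* **Hjorth parameters** — activity is the N−1 sample variance; mobility
  and complexity use the first difference as the discrete derivative with
  no fs scaling, so a sinusoid of frequency f has per-sample mobility
  ≈ 2πf/fs. Values are convention-dependent; this one is fixed and
  documented because classifiers only need consistency.
* **AR coefficients** — order 4, Burg (lattice) estimator, chosen for its
  behavior on short segments; Levinson–Durbin on biased autocovariances
  ("yule_walker") is available as a cross-check route.
* **Fractal dimension** — the box-counting dimension is a limit, not an
  algorithm; the estimator is Higuchi's method with kmax = 10. Smooth
  curves score ≈ 1, white noise ≈ 2; estimates outside [1, 2] are clipped
  with a warning.
* **Approximate / sample entropy** — m = 2, r = 0.2 × the channel's
  standard deviation, Chebyshev template distance. ApEn follows the Pincus
  Φ^m − Φ^(m+1) form with self-matches included; SampEn excludes
  self-matches, compares equal numbers (N−m) of m- and (m+1)-templates,
  and returns +inf with a warning when no matches exist. Both are computed
  from one pair of incrementally built distance matrices, so the two cost
  a single O(N²) pass per channel.
* **Permutation entropy** — order 3, delay 1, natural log, ties ranked by
  temporal order of appearance (stable argsort). A normalized variant
  (÷ log m!) exists but is off by default.
* **Moments** — skewness and kurtosis are the biased 1/N moment ratios
  with the population σ in the denominator, kurtosis as excess (Gaussian
  = 0); variance uses 1/(N−1) and the standard deviation is its root. The
  mixed convention (population σ inside the moment ratios, N−1 variance
  alongside) is intentional and frozen by tests: the two-point sample
  {−1, +1} scores skewness 0, excess kurtosis −2, variance 2, sd √2.

Degenerate inputs (constant channels) produce NaN sentinels and flag the
epoch; flagged epochs are excluded from normalizer fitting and classifier
training rather than imputed. Normalization is a per-feature z-score with
parameters estimated on the training split only; zero-spread features pass
through unscaled with a warning. Normalization statistics are pooled over
the dataset by default (per-subject normalization is a caller decision —
the functions operate on whatever vectors they are given).

Features are per-sample/per-second densities or scale-free ratios wherever
possible, which removes most trial-length dependence; the package does not
truncate or resample trials to a common length.

## MI classification

Six classifiers with pinned hyperparameters, all via scikit-learn: random
forest (100 trees), k-nearest neighbors (k = 5), linear-kernel SVM in a
one-versus-rest arrangement decided by argmax of decision scores, Gaussian
naive Bayes, L2-regularized logistic regression, and a depth-10 decision
tree. The data split is stratified 80/20, reproducible by seed. Evaluation
reports accuracy, macro-averaged precision/recall/F1 and the full
confusion matrix; macro averaging is the right default for the
class-balanced four-class design.

## P300 speller chain

Per intensification: cut [0, 667) ms → band-pass with an 8th-order
Chebyshev type-I filter, 0.1–10 Hz, 0.5 dB passband ripple, implemented as
cascaded second-order sections and applied causally (forward-only), so the
chain remains usable online → decimate by keeping every k-th sample,
k = floor(fs / (2·f_high)); the band-pass is the anti-aliasing filter, so
no extra low-pass is inserted. At the 240 Hz reference rate k = 12 and
160 samples become 14; over 64 channels the channel-major concatenation is
896-dimensional. 240 Hz is only a default — every operation takes fs as a
parameter — but it is the rate at which the 0–667 ms window and the
cutoff-driven decimation jointly produce 14 samples per channel.

Decoding is two-phase. Phase 1 is a binary target/nontarget classifier
(default: the random-forest spec from the shared menu) producing a
monotone P300-ness score per vector. Phase 2 sums raw scores per
row/column id over repetitions and emits the symbol at the intersection of
the best row and best column; ties break toward the lowest id. Summing
scores rather than counting votes uses the classifier's confidence and is
what makes character accuracy rise steeply with repetition count.

## The command controller

The controller is a total deterministic transition table over
(state × {LEFT_HAND, RIGHT_HAND, BOTH_HANDS, REST}). Load-time validation
guarantees totality and that MAIN is reachable from every state, so a user
cannot be trapped in a sub-application; both properties are re-checked for
user-supplied YAML tables. Three transitions are fixed by design — right
hand launches the browser, left hand the OS explorer, both hands the email
client and then its inbox — and the shipped table completes the rest with
a uniform idiom: REST backs out toward MAIN, RIGHT_HAND advances a
highlight, BOTH_HANDS selects. States flagged `text_entry` (compose,
address bar, terminal) tell the caller to switch to the P300 speller;
actions are emitted as strings and never executed by the FSM itself. The
mapping from the four cursor-task classes to thoughts (UP ↔ both hands,
DOWN ↔ rest) is a configuration constant.

## Synthetic data: what it emulates, what it does not

Background activity is per-channel-independent 1/f^α Gaussian noise
(α = 1) synthesized in the frequency domain and scaled to 10 µV RMS — a
realistic resting-EEG amplitude.

**MI sessions** place 10 Hz (10 µV) and 20 Hz (5 µV) rhythms on the C3 and
C4 electrode clusters. Imagined movement attenuates the contralateral
cluster's rhythm amplitude by `erd_depth` (default 0.5; both clusters for
both-hands, neither for rest). ERD is therefore pure amplitude
attenuation; negative `erd_depth` yields ERS. Trials are 3 s at 250 Hz
with 1 s gaps.

**P300 sessions** follow the oddball speller protocol: per character, 15
repetitions of the 12 row/column flashes in fresh random permutations,
0.25 s stimulus onset asynchrony. Target flashes add a positive Gaussian
bump — 5 µV peak, 300 ms latency, 0.1 s FWHM — on eight centro-parietal
channels. At these defaults the phase-1 classifier reaches a single-trial
AUC of roughly 0.85, which is what real spellers achieve; reliable
spelling then comes from repetition averaging, exactly as in practice.

Both generators are pure functions of (config, seed).

What passing tests on this data do **not** show: robustness to artifacts
(blinks, EMG, line noise — no artifact model is included), to spatially
correlated background activity (channels are independent unless the
smoothing option is used), to ERP latency/amplitude variability across
trials, or to non-stationarity across sessions. Accuracies on the
synthetic benchmark characterize the pipeline's mechanics, not expected
performance on human EEG.

## Benchmark problem sizes

The shipped end-to-end checks run at desk scale, chosen once: the MI
bracketing experiment uses the 21-channel motor-strip montage with 100
trials per class (logistic regression exceeds 80 % four-class accuracy at
`erd_depth` 0.8 and sits at chance, 0.25 ± 0.1, at 0); speller bookkeeping
and the 100-character repetition-monotonicity experiment use an 8-channel
centro-parietal cap (epoch and vector counts are channel-independent);
the 10-character recovery check runs at the full 64-channel default. These
sizes are the package's reference configurations for its own test bench.

## Numerical and degenerate-input policy

* Welch band power of a zero signal is 0; bands must lie inside
  (0, fs/2).
* Constant signals: Hjorth activity 0 with NaN mobility/complexity; NaN
  skewness/kurtosis; no AR fit; the owning epoch is flagged.
* SampEn with zero matches returns +inf with a warning rather than
  raising, so one degenerate epoch cannot abort a batch.
* The Chebyshev band-pass refuses fs ≤ 2·f_high and verifies its output is
  finite (SOS form keeps the order-8 design stable at EEG rates).
* Decode ties (equal summed scores) break toward the lowest row/column id;
  classifier score ties are resolved by the underlying argmax order, which
  is fixed and documented rather than randomized.
* All stochastic stages (simulators, splits, tree-based models) take
  explicit seeds; identical seeds give bit-identical outputs.

## Known limitations

* The Laplacian is the unweighted neighbor-mean form, not a spline or
  spherical-harmonic current-source-density estimate.
* No CSP, wavelet or Riemannian features; no channel selection; no
  sliding-window features.
* The speller chain assumes the band-pass precedes decimation; calling
  `decimate_epoch` on unfiltered data aliases by construction.
* EDF support is read-only; events always travel in the sidecar TSV, even
  for EDF files.
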