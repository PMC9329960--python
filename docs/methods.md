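# Methods

## Problem setting

A subject walks a short out-and-back course (a timed-up-and-go, with a
narrow-passage variant to provoke freezing) in front of a fixed
monocular camera. A 2D pose estimator yields, per frame, 25 keypoints
in the BODY_25 layout with confidences. Frame-based annotations mark
turning intervals and FOG intervals; spans where freezing cannot be
asserted with certainty are marked *unknown* and excluded from both
training and scoring. All frame intervals are 0-based half-open
`[start, end)`.

## Preprocessing

**Dropout repair.** Keypoint-frames with confidence below
`conf_min = 0.1` are repaired by per-channel linear interpolation in
time between the nearest confident frames (nearest-value fill at the
edges). Repaired confidences are set to `conf_min`, which makes the
operation idempotent. How occluded keypoints were handled upstream is
generally unknowable from the keypoint files alone; linear
interpolation is the minimal assumption and the repair fraction is
reported per sequence.

**Scale normalization.** Per frame: the minimum axis-aligned rectangle
over keypoints with positive confidence; width and height each expanded
by 30%, symmetric about the rectangle center; translation so the
expanded rectangle's upper-left corner is the origin; multiplication by
`s = 80 / expanded height`. Two deliberate readings of an ambiguous
recipe: the height in `s` is the *expanded* rectangle's height (the
same rectangle that defines the origin), and normalization is per frame
rather than per clip, since its purpose is to cancel the within-clip
apparent-size change as the subject approaches the camera. The
construction is exactly invariant to isotropic scaling and translation
of the raw pixels (property-tested).

**Signal bank.** Positions, speeds and accelerations per keypoint and
axis (forward first difference × fps, last sample replicated), interior
knee angles in degrees, and the absolute left–right x-separation of
8 keypoint pairs (hips, knees, ankles, big toes, shoulders, elbows,
wrists, ears). Pair differences use the x-axis only: under a frontal
camera a turn collapses exactly these separations. No low-pass filter
is applied before differencing by default; a 15 Hz zero-phase
Butterworth filter is available behind a flag (`lowpass_hz`) since at
30 fps the Nyquist limit already caps content at 15 Hz.

## Features

Windows are 2 s long with a 0.1 s step (sample-exact arithmetic:
`count = (N − n)//step + 1`). Stage label is *turn* when more than half
of a window's frames lie in turn intervals; the FOG label is *unknown*
if the window touches any unknown span, else *fog* when at least 50% of
its frames are annotated FOG.

Time-domain statistics per window: min, max, mean, mean of absolute
values, mean square, peak-to-peak, 90th percentile (linear-interpolated
order statistic at position 1+0.9(n−1)), population skewness
(0 when σ = 0), the *non-central* kurtosis coefficient Σx⁴/n (kept
non-central deliberately — it doubles as a scale-sensitive magnitude
feature), crest factor max(x)/RMS (0 when RMS = 0), clearance factor
max|x| / (mean √|x|)² (a literal crest-factor duplicate is available via
`clearance_as_crest` for strict compatibility with sources that print
them identically), Shannon entropy of a 10-bin window histogram, and
the minimum squared sample.

The spectrum estimator is a rectangular-window periodogram of the
mean-removed window (n = 60 at 30 fps): amplitudes are |rDFT|
magnitudes; the one-sided power density is normalized so that
Σ power·Δf equals the window variance (Parseval-consistent, tested
against a direct-summation DFT oracle at 1e-9). Spectral features:
amplitude peak, power-weighted mean frequency (the robust
interpretation of an "average frequency" over complex coefficients),
second-largest local maximum of power (0 if none), trapezoidal band
powers over 0.5–3 Hz, 1–1.5 Hz and 3.5–15 Hz (upper edges clipped to
Nyquist; edge interpolation makes band powers exactly additive), and
the freezing index FI = P(3–8 Hz)/P(0.5–3 Hz), capped at 1e6 when the
locomotor power is numerically zero (< 1e-12). Normal stepping places
its energy in the locomotor band; freezing suppresses it and often adds
6–8 Hz leg trembling, so FI separates the regimes by orders of
magnitude.

## Models

Three binary XGBoost classifiers: motion (walk vs turn, trained on all
labeled windows including FOG), Walk-FOG (walking-stage windows) and
Turn-FOG (turning-stage windows). The FOG models get a training-only
pipeline, in order: transition-window removal (windows *starting*
within 0.5 s of an annotated FOG boundary are dropped — their labels
are ambiguous; test folds are never filtered), SMOTE oversampling of
the FOG class to parity (synthetic rows are convex combinations of
minority nearest neighbors, k = 5, subject group inherited from the
base row), gain-ranked forward feature selection, and grid search.
Feature caps are 50 (motion), 20 (Walk-FOG) and 12 (Turn-FOG).

Forward selection adds features in total-gain order and scores each
prefix by subject-grouped cross-validation GM; the best prefix wins,
ties to the smaller prefix. When grouped scoring is degenerate (too few
FOG subjects in a training split for any grouped fold to contain both
classes on both sides) the selection keeps the capped gain-ranked
prefix and the single-point grid is fitted directly, with warnings —
an honest fallback rather than a silent arbitrary choice.

During training the stage routing uses the annotated stage; at
inference the motion model's prediction routes each window to the
Walk-FOG or Turn-FOG model. The FOG decision threshold on the
predicted probability is 0.5.

The FOG duration threshold is the 10% linear-interpolation quantile of
the annotated FOG episode durations *of the training subjects of each
fold* — computing it over all annotations would leak test labels.
Predicted FOG runs shorter than the threshold are relabeled non-FOG.

The default hyperparameter grid spans learning_rate {0.05, 0.1, 0.3},
n_estimators {50, 100, 200}, max_depth {3, 5, 7}, subsample {0.8, 1.0},
colsample_bytree {0.8, 1.0}. The desk-scale configuration
(`ModelConfig.fast()`), used by the test suite and the acceptance
script, fixes a single grid point (0.1 / 30 / 3 / 1.0 / 1.0), coarsens
the forward-selection ladder to 9 prefix sizes, and lowers the
histogram resolution to 32 bins; these are configuration choices for a
12-subject synthetic study, not changes of method.

## Episode evaluation

Consecutive windows with equal FOG decisions merge into episodes
spanning first-window start to last-window end; a gap in the window
stream larger than the step splits runs. The truth partition of a
recording's timeline alternates FOG/non-FOG episodes with unknown spans
cut out.

A window is attributed to the truth episode containing its **midpoint**
— the same majority logic that labels windows. Episode sensitivity is
the fraction of truth FOG episodes containing at least one
predicted-FOG window; episode specificity the fraction of truth
non-FOG episodes containing none; accuracy the fraction of episodes
correct; GM = √(sens·spec) everywhere (the identity
GM² = sens × spec is asserted to 1e-12). Midpoint attribution is a
considered choice: attribution by *span overlap* is degenerate for
specificity, because a correctly predicted 2 s boundary window always
overlaps the neighboring non-FOG episode, so even a perfect classifier
would be charged a false positive at every FOG boundary. Window-level
metrics (with a midrank-AUC) are reported for the motion model.

LOSO discipline: one fold per subject; ranking, SMOTE, selection, grid
search and the duration threshold see only training subjects (verified
by fingerprinting the training rows per fold). Pooled (micro) metrics
over the union of held-out windows/episodes are the headline numbers;
per-fold metrics are retained. The experiment driver runs the
multi-stage pipeline and a non-staged single FOG model (same feature
pipeline, no stage routing, cap 20) on identical folds and reports
both.

## Synthetic cohort

The generator emulates exactly the structure the pipeline measures,
with stylized (sinusoidal) kinematics rather than biomechanics:

* **walking** — limb keypoints oscillate at a per-subject cadence
  (uniform 0.8–1.2 Hz) with left/right antiphase, amplitude ~5% of
  body height; apparent scale ramps across 1.0–1.5× within walking
  segments (camera-distance change), alternating direction per segment;
* **turning** — all left–right x-offsets scale by |cos(πu)| across the
  turn (collapse and re-expansion), translation paused;
* **FOG** — locomotor amplitude × 0.05, lower-limb keypoints gain a
  6–8 Hz tremor (amplitude ~2% of body height), progression arrested.
  The regime ramps in and out over 0.6 s (raised cosine) inside the
  annotated interval: freezing onset and release are gradual, which is
  the very reason transition windows are removed from training — a
  hard kinematic step would make majority-non-FOG boundary windows
  look fully frozen, an artifact no real annotation protocol produces;
* plus Gaussian pixel jitter (σ = 1 px) and 1% keypoint dropouts
  (confidence 0).

Defaults mirror the clinical study conditions where stated: 30 fps,
two recordings per subject (standard and narrow course), 26% of
subjects with FOG (ceiling of prevalence × n), 1–4 episodes per
affected subject with ~25% placed in turns, episode durations uniform
in 1–15 s (clipped into their segment). Segment lengths (walk 8–11 s,
turn 2–3 s per segment, walk→turn→walk plan) are chosen so a
12-subject cohort stays desk-scale. Annotations are exact by
construction.

What passing tests on this cohort do **not** show: robustness to pose
estimator failure modes (identity switches, severe occlusion),
biomechanical FOG phenotypes (trembling vs akinetic), camera
obliquity, or medication-state effects. The simulator's separability
is by design stronger than clinical video; synthetic recovery rates
validate the pipeline's correctness, not its clinical accuracy.

## Statistical test

Windows are autocorrelated and subjects differ in baseline, so group
differences in a feature are tested on one mean per subject per group
with the paired Wilcoxon signed-rank test (exact null for small n via
scipy; all-zero differences return p = 1 with a degeneracy flag;
subjects missing a group are dropped and counted, at least 5 usable
pairs required).

## Numerical and engineering notes

* All randomness flows from one seed: simulation, SMOTE, tree fitting
  and grid tie-breaks; reruns produce byte-identical metrics JSON.
* Ties in grid search resolve to the first point in deterministic
  (sorted-key product) order; zero-gain features rank last
  alphabetically.
* Degenerate inputs: zero-height bounding rectangles, dead keypoint
  channels, single-class training labels, and all-FOG-free training
  sets either raise typed errors or fall back to flagged constant
  non-FOG predictors.
* Band integrals interpolate the power density linearly at band edges;
  the 3.5–15 Hz band is exactly representable at 30 fps.
* Serialized bundles store native boosters plus a YAML manifest of
  selected features, thresholds and provenance (config, seed, training
  fingerprint).

## Known limitations

* The motion model sees near-perfect synthetic separation; real
  walk/turn boundaries are soft and would lower its rates.
* Episode specificity depends on the duration threshold learned per
  fold; with very few training FOG episodes the 10% quantile is noisy.
* The simulator does not model multi-person scenes, so the
  largest-bounding-box person policy is exercised only by unit
  fixtures.
* Camera affine correction and real-video ingestion are out of scope;
  inputs are keypoint files, not video.
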