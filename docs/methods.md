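# Methods

This note documents the models, conventions and numerical choices behind
`dlahar`, and what the synthetic cohort does and does not establish.

## Data model and conventions

A recording is a block of 24 equal-length channels — four nodes (WRIST,
CHEST, HIP, ANKLE) × six channels (ax, ay, az, gx, gy, gz) — at one common
sampling rate (default 204.8 Hz). Accelerometers are in g (±6 g range),
gyroscopes in deg/s (±500 deg/s; ±2000 deg/s at the ankle, where larger
angular velocities occur). Calibration from raw ADC counts is assumed done
upstream.

Time is in seconds from the start of the recording. Sample index =
round(t × rate), and all sample intervals are half-open `[start, end)`.
This matters because 204.8 Hz makes 2 s equal 409.6 samples; rounding to
the nearest sample is the documented and tested behavior.

Storage formats are a CSV bundle (one `<NODE>.csv` per node with header
`t,ax,ay,az,gx,gy,gz`, plus `meta.json` with subject id and rate, labels in
`labels.csv` as `activity,t_start,t_end`) and an HDF5 layout
(`/subject_id`, `/rate`, `/nodes/<POSITION>/<channel>`). HDF5 round trips
are bit-exact; CSV round trips are exact to the textual precision written.

## Synchronization and trimming

Recordings begin with all nodes on a plate that is dropped twice with an
up-down movement in between. Instead of picking the alignment point by
hand, `detect_sync_start` finds the first sample whose vertical
acceleration deviates from the resting baseline (median of the first
0.5 s) by more than a threshold, 1 g by default. The threshold is a
package choice — the event is a multi-g excursion, handling noise is well
below 1 g — and a manually chosen index can be supplied instead via
`apply_sync`. Each labeled segment is then trimmed by 2 s at both ends to
remove labeling jitter; segments that become empty are discarded.

## Windowing

Windows are 5 s with 50% overlap (1024 samples, hop 512 at the native
rate). Windowing restarts at each labeled segment, so no window spans two
activities, and trailing partial windows are dropped rather than padded —
fixed-length windows are required downstream and padding would distort
spectra. A segment of S samples yields `floor((S − W)/H) + 1` windows
(0 if S < W). `resample_linear` (linear interpolation on the uniform time
grid) is provided for down-sampling to the rates used by comparison
methods.

## Feature sets

**Generic, 152 features.** Per axis: minimum, maximum, mean, variance,
spectral centroid, spectral bandwidth; per node and sensor type: energy.
Conventions that the source method leaves open and that this package fixes:

* Variance is population variance (1/N). Consistency matters more than the
  estimator convention at N = 1024.
* Spectral centroid/bandwidth use *magnitude* (not power) weighting on the
  one-sided FFT of the mean-removed window, rectangular taper, DC bin
  excluded. A window whose mean-removed spectrum is identically zero
  (constant window) returns (0, 0) by convention.
* Energy is computed on raw-unit signals; accelerometer and gyroscope
  energies are not normalized against each other. Scale adaptation is left
  to the classifier stage.

Feature names (`<node>.<channel>.<feature>`, `<node>.<type>.energy`) and
their order are fixed, so matrices are comparable across runs.

**REST, 12 features.** The gravitational component of each accelerometer
axis, extracted with a third-order elliptic IIR low-pass, cut-off 0.25 Hz.
Design margins default to 0.01 dB passband ripple and 100 dB stopband
attenuation and are configurable. Filtering is causal (single forward
pass), mirroring the real-time lineage of the design, and is applied to the
continuous per-segment signal *before* windowing; the per-window feature is
the mean of the filtered samples (the per-window reduction is a package
choice). The filter state is initialized to the steady state of the first
sample, which removes the step transient for signals starting near their DC
level; residual warm-up is on the order of 1/cutoff = 4 s, well inside a
trimmed segment.

## Hierarchy and classifiers

BASE is a 6-class problem over the full window set (HOUSE, REST, WALK,
BICYCLE, WD, RJ); each group subsystem is trained only on windows of its
member activities; REST consumes the 12-feature set, all others the
152-feature set. At prediction time, singleton BASE outputs are final and
group outputs are resolved by the corresponding subsystem; a misrouted
window receives the forced prediction of the (wrong) subsystem, so the
final output is always one of the 13 activities and routing errors appear
as off-diagonal blocks of the confusion matrix.

Classifier families and fixed hyperparameters: AdaBoost with 100
decision-stump learners (multi-class SAMME), CART (Gini, no depth limit),
kNN with k = 5 (uniform votes; exact vote ties are resolved by the
library's class order — with continuous features they have probability
zero), and an RBF-SVM with C = 1 and gamma = 1/n_features of the model at
hand (one-vs-one multiclass). kNN and SVM inputs are z-scored per feature,
with the scaler fit on the training portion of each fold only; trees and
boosting consume raw features. Whether to standardize is a
reproduction-sensitive choice the source method does not state; distance
and kernel methods are not meaningful across units of g and deg/s without
it. A single seed controls all stochastic classifier internals, making
training deterministic.

`select_best_classifiers` re-runs, for each of the five subsystems, a LOSO
evaluation of all four families *on that subsystem's own problem* and keeps
the family with the highest overall mean rate; exact ties break by the
fixed order SVM > kNN > AdaBoost > CART. The shipped defaults are the
published winners (SVM for BASE/REST/BICYCLE, AdaBoost for HOUSE, kNN for
WALK).

## Evaluation

LOSO: one fold per subject; in each fold *every* level of the hierarchy is
retrained without the held-out subject, so no information leaks across
levels. Per-fold confusion matrices (13×13, fixed activity order) are
summed. Per-class rate = 100 × diagonal / row sum; overall mean = macro
mean of defined class rates. Rates are computed in full precision and
reported at one decimal. A class with no evaluated epochs is flagged with
a warning and excluded from the macro mean; this arises only on degenerate
inputs.

## Synthetic cohort

The generator exists to verify the pipeline and to support
parameter-recovery experiments; it is deliberately not a biomechanical
model. Archetypes per activity category:

* postures: constant per-node gravity projection (distinct orientations
  for sitting/lying/standing) plus Gaussian sensor noise;
* locomotion and sports: a harmonic series at an activity-specific
  fundamental (walking 2.0 Hz, stairs 1.4/1.8 Hz, running 2.8 Hz, rope
  jumping 2.3 Hz) with node-specific amplitudes — ankle gyroscope dominant
  for gait, large vertical hip acceleration for rope jumping; stair ascent
  and descent additionally differ by opposite waveform skew (phase-shifted
  harmonics), standing in for the inclination information an ankle
  gyroscope carries;
* household: wrist-dominant oscillation plus band-limited (< 6 Hz) motion
  noise;
* bicycling: smooth ~1.17 Hz (70 rpm) periodicity, the 100 W level scaled
  from the 50 W level by a configurable amplitude ratio (default 1.6;
  1.0 makes the levels statistically identical);
* every channel additionally carries a slow (< 0.3 Hz) postural sway of
  0.02–0.05 g on the accelerometers. Without it, per-subject gravity
  offsets make window means zero-variance within subject, which no real
  recording exhibits and which destabilizes standardized kernel methods
  under LOSO;
* each recording starts with the plate-drop pattern used by the
  synchronization detector.

Inter-subject variability is drawn deterministically from (seed, subject
index): amplitude factor (log-normal, σ = 0.06), cadence factor (±4%),
a small rigid rotation of all gravity vectors (up to 8°), and a noise
scale. Generated signals are checked against the sensor ranges; violations
raise rather than clip silently.

Bout durations default to the benchmark protocol (1 min for postures,
vacuuming, sweeping; 2 min for washing dishes, running and both bicycling
levels). For the four bouts whose protocol duration is not fixed, the
defaults are matched to the benchmark's per-subject epoch inventory:
walking 270 s (a campus transfer, by far the largest class), stairs
40/35 s, rope jumping 32 s. This preserves the benchmark's class-imbalance
structure (walking ≫ two-minute activities ≫ one-minute activities ≫
stairs/rope jumping).

**What passing tests show — and don't.** On the default six-subject cohort
the full LOSO hierarchy exceeds 95% macro mean, and collapsing the
bicycling amplitude ratio to 1.0 drives the BICYCLE subsystem toward
chance while BASE stays above 95% — the qualitative signature of an easy
grouping with a hard within-group split. These results validate the
pipeline's mechanics (windowing, features, routing, fold hygiene), not
real-world performance: the archetypes are far cleaner than human movement,
with no transitions, drift, sensor misplacement, or within-bout
nonstationarity beyond slow sway. Absolute rates on real recordings will be
lower, particularly for vacuuming vs sweeping and the bicycling levels.

## Problem sizes and tolerances

Tests and the acceptance script use six simulated subjects at the native
204.8 Hz and full default durations (~425 windows per subject), chosen so
a complete run finishes in minutes on one CPU. Elementary feature
operations are verified against brute-force oracles at 1e−12; spectral
closed forms on bin-aligned sinusoids at 1e−9 for centroids, with a 1e−4 Hz
allowance on bandwidths (the square root amplifies float64 spectral
leakage); filter DC gain within ripple after warm-up; and metric
recomputation from the published benchmark confusion matrix to the printed
one-decimal precision.

## Known limitations

* The spectral centroid of noisy, harmonic-rich channels sits well above
  the movement fundamental under magnitude weighting; the generator's
  cadence is therefore recovered by the dominant spectral peak, not the
  centroid itself.
* kNN tie handling follows scikit-learn; a bespoke nearest-neighbor
  tie-break would only matter on discrete features.
* The generator shares one activity schedule across subjects (order and
  durations); only signal content varies.
* No streaming/online prediction; the model archive is a fitted in-memory
  hierarchy plus its configuration, serialized by the caller if needed.
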