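# Methods

## Problem and scope

`armgait` scores arm movement abnormality during walking from 2D landmark
time series. It deliberately begins *after* pose estimation: the input is a
per-frame `(x, y, likelihood)` record for eight landmarks (bilateral
shoulder, elbow, wrist, hip) from a front-facing camera, and the package
takes no position on how those landmarks were produced. Everything the
package computes — trimming, angles, features, the classifier, the
agreement statistics — operates on that representation alone.

## Trimming model

A recorded trial has three phases: standing (before the walk), walking
toward the camera, and a terminal phase in which the subject is too close
and landmarks leave the frame.

**Onset.** As the subject approaches a fixed camera, every inter-landmark
pixel distance grows roughly as 1/distance. The detector monitors the
shoulder-pair and hip-pair widths, takes their median over the first
`baseline_window` frames as the standing baseline, and declares the walk to
begin at the first frame whose width exceeds
`baseline x (1 + rise_fraction)` for `confirm_frames` consecutive frames.
Two guards make this robust to landmark jitter, and both vanish on clean
input: the widths are smoothed with an 11-frame running median before
thresholding (the median of a monotone window is the identity, so a clean
ramp is unchanged), and the threshold is raised by `noise_guard_mads`
MAD-scaled units of the baseline-window jitter (exactly zero when the
baseline is noise-free). With the defaults (`baseline_window = 30` frames,
`rise_fraction = 0.05`, `confirm_frames = 3`, `noise_guard_mads = 3`), the
detector locates the scripted onset of synthetic trials 13-44 frames
(0.4-1.5 s at 30 fps) after the true first step and never fires during the
standing phase. A 10-frame baseline was tried first and rejected: at 10 m
distance a 2 px landmark jitter is ~7% of the standing shoulder width, and
ten frames are too few to estimate that noise floor reliably.

A subject already mid-walk at frame 0 is a boundary case: the baseline
itself is then contaminated by growth, and the onset lands within the
baseline window rather than at frame 0. This is inherent to defining the
baseline from the recording's own first frames.

**End.** A landmark is *lost* in a frame when its likelihood is below
`likelihood_threshold` (default 0.6) or a coordinate is non-finite. The
retained segment ends at the first frame of the earliest run of **more than
two** consecutive lost frames for any landmark; a two-frame loss is
tolerated (and later absorbed by the median filter), a three-frame loss is
not. The boundary is exact and covered by an exhaustive-scan oracle test.

**Filtering.** Retained landmark x and y series are filtered with a
three-point running median (edge replication at both ends, so output length
equals input length); this removes single-frame estimation spikes without
smearing genuine motion. Likelihoods are never filtered, and joint-angle
series are computed from the filtered coordinates but never filtered
themselves. Segments shorter than `min_retained_frames` (default 20,
i.e. two thirds of a second — too short for stable summary moments) are
rejected.

## Kinematics

All angles are unsigned: `arccos` of the normalised dot product, range
[0°, 180°]. A frontal-plane projection cannot reliably distinguish flexion
direction, so no sign is imposed.

* Elbow angle: at the elbow vertex between elbow→wrist and elbow→shoulder;
  180° = fully extended. This is the clinical goniometry convention; the
  alternative reading (angle between undirected segment axes, which folds
  at 90°) was rejected because it conflates mild and extreme flexion.
* Trunk axis: unit vector from the shoulder midpoint to the hip midpoint,
  recomputed every frame (no temporal averaging — the construction is
  per-frame geometric).
* Shoulder angle: between shoulder→elbow and the trunk axis; 0° = arm
  hanging parallel to the trunk, 90° = horizontal. A frontal-plane
  abduction proxy.

Both constructions are invariant to translation and uniform scaling of the
image (camera-distance independence) and equivariant under left-right
mirroring; these properties are tested exactly, and the numeric values are
tested against an independent `atan2(|cross|, dot)` oracle to 1e-9 degrees
on 1000 random poses. Frames in which any of the four angles is undefined
(zero-length segment, non-finite landmark) are dropped from all four series
jointly, keeping the series aligned.

## Features and labels

Each of the four angle series reduces to max, min, mean, SD, skewness and
kurtosis: 24 features per trial. Conventions: SD uses the n−1 denominator;
skewness is the Fisher third standardised moment and kurtosis is excess
kurtosis, both as biased moment estimators; a constant series has
sd = skew = kurt = 0 by convention. The label is the median of the
assessors' integer scores — for an odd assessor count the median is itself
an ordinal score; an even count producing a half-integer is rounded half
down (toward less severity) with a warning.

## Classifier and validation

A scikit-learn pipeline (StandardScaler → RandomForestClassifier) treats
the five scores as classes. Generalisation is estimated by nested
cross-validation: 5 outer folds; within each outer training set, a grid
search over {trees 100/300/500} × {depth none/5/10} × {min leaf 1/3/5}
scored by inner 5-fold CV accuracy; the winning pipeline is refit on the
whole training portion and predicts the held-out fold. The scaler is part
of the pipeline, so its mean/variance are always fitted inside whatever
training split is current — the leakage test asserts this fold by fold.

Folds default to grouping by participant (all of a person's trials share a
fold), because participants contribute two trials and splitting them across
folds lets the forest recognise the person rather than the impairment;
`by_trial` splitting is available for comparison. With a fixed
`random_seed`, fold assignment, selected hyperparameters and predictions
are bit-reproducible.

`fit_final` refits on all rows (grid search by full-data inner CV) for
deployment-style use; its resubstitution accuracy upper-bounds the
out-of-fold estimate and is reported as such, never as generalisation.

## Agreement battery

For a prediction vector against a reference (median assessor or a single
assessor): exact-match accuracy (percent), MSE, the tally of
|pred − ref| ∈ {0..4}, quadratic weighted Cohen's kappa, a one-sample
t-test on the differences (negative mean = under-prediction) with
Cohen's d = mean/SD, and one-way ANOVA across model variants' difference
scores. Kappa uses agreement weights w_ij = 1 − (i−j)²/16 over the full
0-4 grid even when some categories are unused. Its standard error comes
from a seeded nonparametric bootstrap over rated items (default 2000
resamples) — assumption-free and directly testable; the large-sample
asymptotic formula is available behind `se_method="asymptotic"`. If both
raters use a single category, kappa is undefined and flagged rather than
silently 0 or 1.

Binary agreement collapses scores to impaired (≥ 2) / unimpaired (≤ 1) and
reports recall TP/(TP+FN), precision TP/(TP+FP), accuracy (TP+TN)/total and
F1 = 2PR/(P+R); zero-denominator ratios are NaN with a named flag. Percent
metrics print to 1 d.p. and ratios to 2 d.p. in the structured report.

## Synthetic cohort generator

The generator exists so the whole pipeline is testable without clinical
video, and its defaults are the study conditions the pipeline targets: 42
affected participants + 34 healthy controls, two trials each, a 10 m
walkway filmed at 1920×1080/30 fps from 0.5 m past its end, three assessors,
and ratings restricted to all affected trials plus five control videos.

Per trial: a 2 s standing prefix; a constant-speed approach (1.1 m/s) that
drives the pixel scale as focal/distance; arms modelled as a frontal-plane
projected sinusoid (0.9 Hz, antiphase) on a rigid trunk. Severity s on the
affected side reduces swing amplitude by a factor (1 − 0.22 s), lowers the
elbow baseline by 11° per step (held flexion) and raises the shoulder
baseline by 6.5° per step (abduction) — monotone offsets chosen so the
feature→severity mapping is learnable by construction and the per-step
effect (≈ 6-11°) is comparable to the per-frame angle noise induced by a
2 px landmark jitter, which matches the pixel error reported for trained
pose networks at this resolution. Dropout: isolated single-frame likelihood
dips (never two in a row, so they never trigger the end rule) plus a
scripted permanent loss — wrists first, everything half a second later —
once the subject is within 1.6 m of the camera. Assessors report
round(severity + N(0, 0.6)) clipped to [0, 4]; σ = 0.6 yields the
exact-agreement rate between raters of a discretised Gaussian, verified
analytically in the tests, and sits in the "moderate reliability" regime.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: biomechanical gait (no double support, no
trunk rotation, no out-of-plane arm motion), pose-network failure modes
other than isotropic jitter and dropout (identity swaps, occlusion-locked
drift), camera distortion, and assessors whose errors are correlated or
severity-dependent. Results on synthetic cohorts demonstrate that the
pipeline recovers the structure it assumes; they are not a clinical
validation.

## Problem sizes and runtime choices

The test suite and the acceptance script keep simulations at desk scale as
a design choice: unit tests use cohorts of ~10 participants; the severity
recovery check uses 150 rated trials (73 affected participants × 2 + 4
controls) with a reduced grid ({100 trees} × {depth none/5} × {leaf 1/3}),
which preserves the nested structure while keeping a full run in seconds.
The full default grid is exercised through the CLI and remains the
recommended setting for real analyses.

## Known limitations

* The elbow/shoulder angles are 2D projections; genuine 3D abduction and
  flexion are confounded with body rotation relative to the camera.
* The onset detector assumes an initially stationary subject and a camera
  the subject approaches; side-view recordings violate its premise.
* The ordinal model is a plain multiclass forest; ordinality enters only
  through the evaluation (quadratic kappa, MSE), not the loss.
* Kappa's bootstrap SE is item-resampled and ignores any participant-level
  clustering of trials.
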