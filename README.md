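# armgait

Automated scoring of **arm movement abnormality during walking** from
marker-less pose-estimation output.

After an acquired brain injury (stroke, traumatic brain injury), many people
walk with a visibly abnormal arm: reduced arm swing, the elbow held flexed,
the shoulder abducted. Clinicians rate this on the ICF qualifiers scale
(0 = no problem … 4 = complete problem) by watching the person walk — a
subjective call with only moderate inter-rater reliability even among
experienced raters. `armgait` implements the downstream half of a two-level
assessment: given per-frame 2D landmark coordinates for the shoulders,
elbows, wrists and hips (as produced by a pose-estimation network from a
front-facing gait video), it reproduces a clinician-style ordinal score and
quantifies how well that reproduction agrees with human assessors.

The pipeline:

1. **Trim** each trial to the walking portion. Walk onset is the first
   sustained rise of the shoulder/hip pixel width over its standing baseline
   (the body image grows as the subject approaches the camera); the trial
   ends at the first run of more than two consecutive frames in which any
   landmark is lost (low likelihood or off-frame).
2. **Filter** each landmark coordinate series with a three-point running
   median (joint-angle series are never filtered).
3. **Kinematics**: per frame, the frontal-plane elbow angle
   θ<sub>elbow</sub> = ∠(elbow→wrist, elbow→shoulder) and shoulder angle
   θ<sub>shoulder</sub> = ∠(shoulder→elbow, trunk axis), where the trunk
   axis runs from the shoulder midpoint to the hip midpoint. Angles are
   unsigned, in [0°, 180°], and invariant to camera distance.
4. **Features**: each trial reduces to 24 values — max, min, mean, SD, skew
   and kurtosis of the four angle series.
5. **Model**: a random-forest classifier predicts the median assessor score,
   with features standardised to zero mean / unit variance and
   hyperparameters tuned by **nested cross-validation** (k = 5 outer folds;
   an inner CV grid search inside each training set, so the held-out fold
   never influences scaling or model selection).
6. **Agreement battery**: exact-match accuracy, mean square error, the
   |prediction − reference| tally, quadratic weighted Cohen's kappa
   (weights w<sub>ij</sub> = 1 − (i−j)²/(k−1)²) with a bootstrap standard
   error, a one-sample t-test with Cohen's d for over/under-prediction,
   one-way ANOVA across model variants, and — after binarising to
   *impaired* (score ≥ 2) vs *unimpaired* (≤ 1) — recall, precision,
   accuracy and F1.

Because raw clinical video is not redistributable, the package ships a
first-class synthetic-cohort generator (`armgait.synth_gait`) that emulates
the recording geometry (approach toward a fixed 1920×1080 camera, stationary
pre-walk prefix, landmark jitter, end-of-trial dropout), severity-dependent
one-sided arm changes, and three noisy assessors — with full ground truth,
so every stage is testable end to end.

## Worked example

```bash
armgait simulate --seed 5 --out cohort/
armgait extract --out extracted/ cohort/pose/*.csv
armgait evaluate --features extracted/features.csv \
                 --ratings cohort/ratings.csv --seed 5 --out eval/
```

With the default cohort (42 affected participants and 34 healthy controls,
two trials each; all affected trials and five control videos rated by three
simulated assessors), the final command prints

```
mean outer-fold accuracy 0.776; report -> eval/report.json
```

and `eval/report.json` contains (abridged)

```json
{
  "accuracy_pct": 77.5, "mse": 0.26,
  "kappa": 0.91, "kappa_se": 0.02,
  "t_stat": -2.351, "p_value": 0.0209, "cohens_d": -0.249,
  "recall": 0.88, "precision": 0.94, "binary_accuracy": 0.9, "f1": 0.91,
  "diff_tally": {"0": 69, "1": 19, "2": 1, "3": 0, "4": 0},
  "fold_accuracies": [0.7778, 0.8333, 0.6667, 0.7778, 0.8235]
}
```

Read: the model reproduces the median assessor score exactly on 77.5% of
held-out trials (folds grouped by participant, so no person appears in both
train and test); nearly all misses are off by a single scale step, and
agreement is near ceiling once scores are collapsed to
impaired/unimpaired. `kappa` is chance-corrected ordinal agreement between
predictions and the median assessor label; the negative `t_stat` says this
run slightly under-predicts relative to the assessors (small effect,
|d| ≈ 0.25).

### Input formats

* **Pose CSV** (native pose-tool dialect): three header rows
  (`scorer`, `bodyparts`, `coords`), then one row per frame with
  `x, y, likelihood` triples per bodypart. Bodypart names are mapped
  through a configurable alias table (`LSHO` → `L_shoulder`, …).
* **Flat CSV**: columns `L_shoulder_x, L_shoulder_y, L_shoulder_likelihood,
  …` (likelihood columns optional), one row per frame.
* **Ratings CSV**: `trial_id, participant_id, assessor_id, score` with
  integer scores 0–4.

All eight landmarks are required: left/right shoulder, elbow, wrist, hip.

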