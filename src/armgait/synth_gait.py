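"""Synthetic gait-landmark cohorts with known severity ground truth.

Emulates the recording setup the pipeline expects: a subject stands still,
then walks a ~10 m walkway toward a fixed front-facing 1920x1080 camera, so
the pixel distance between paired landmarks grows as 1/distance; near the
camera, landmarks start leaving the frame.  Arm movement abnormality is
modelled as severity-dependent, one-sided changes in the frontal-plane arm
pose: reduced arm-swing amplitude, a held elbow-flexion offset and a
shoulder-abduction offset, all increasing linearly with the true severity
(0 = none ... 4 = complete).  Landmark pixel jitter emulates pose-estimation
error, isolated single-frame dropouts emulate transient detection failures,
and a permanent landmark blackout near the camera emulates the subject
walking out of frame.

Ratings come from simulated assessors whose score is the true severity plus
Gaussian noise, rounded and clipped to 0..4 — a crude but testable stand-in
for moderately reliable expert raters.

The generator is a closed-form script plus seeded noise: every quantity the
pipeline should recover (walk onset frame, blackout frame, per-frame angle
series, true severity) is available for oracle-style testing.  It renders no
images and models no sagittal-plane or lower-limb mechanics — fidelity
beyond what the 2D frontal-plane pipeline consumes would be wasted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SynthConfig, config_dict
from .landmark_io import LANDMARKS, LandmarkTrace, write_pose_csv, write_ratings


@dataclass
class TrialTruth:
    """Ground truth for one simulated trial."""

    trial_id: str
    participant_id: str
    group: str
    severity: int
    affected_side: str           # "L" or "R" (irrelevant at severity 0)
    onset_frame: int             # first frame of scale growth
    blackout_frame: int          # first frame of the permanent landmark loss
    n_frames: int
    angles: Dict[str, np.ndarray]  # noise-free elbow/shoulder series, degrees


@dataclass
class Cohort:
    traces: List[LandmarkTrace]
    ratings: pd.DataFrame
    truth: pd.DataFrame
    manifest: dict


def _arm_schedule(cfg: SynthConfig, severity: int, affected: bool,
                  t_walk: np.ndarray, phase0: float) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free (shoulder_angle, elbow_angle) series in degrees."""
    sev = severity if affected else 0
    swing = cfg.swing_amplitude_deg * max(0.05, 1.0 - cfg.swing_reduction_per_severity * sev)
    sho0 = cfg.shoulder_baseline_deg + cfg.abduction_per_severity * sev
    elb0 = cfg.elbow_baseline_deg - cfg.elbow_flexion_per_severity * sev
    walking = t_walk >= 0
    phase = 2 * np.pi * cfg.stride_hz * np.where(walking, t_walk, 0.0) + phase0
    osc = np.where(walking, (1 + np.sin(phase)) / 2, 0.0)  # in [0, 1]
    shoulder = np.clip(sho0 + swing * osc, 0.0, 178.0)
    elbow = np.clip(elb0 - 0.5 * swing * osc, 2.0, 178.0)
    return shoulder, elbow


def simulate_trial(
    config: SynthConfig,
    participant_id: str,
    trial: int,
    seed: int,
    severity: int,
    affected_side: str = "L",
    group: str = "ABI",
) -> Tuple[LandmarkTrace, TrialTruth]:
    """Simulate one walking trial; deterministic given ``seed``.

    The trace contains (a) a stationary prefix, (b) an approach phase in
    which all inter-landmark pixel distances grow as the subject nears the
    camera, (c) sinusoidal arm swing with severity-dependent one-sided
    offsets, (d) Gaussian landmark jitter and (e) likelihood dropout, both
    isolated single frames and a permanent loss once the subject is within
    ``blackout_distance_m`` of the camera.
    """
    if severity not in range(5):
        raise ValueError(f"severity must be in 0..4, got {severity}")
    if affected_side not in ("L", "R"):
        raise ValueError("affected_side must be 'L' or 'R'")
    rng = np.random.default_rng(seed)

    fps = config.fps
    prefix = int(round(config.stationary_s * fps))
    walk_frames = int(np.ceil((config.start_distance_m - 0.5)
                              / config.walk_speed_mps * fps))
    T = prefix + walk_frames
    t = np.arange(T)
    t_walk = (t - prefix) / fps                      # seconds since walk onset
    Z = np.where(t < prefix, config.start_distance_m,
                 np.maximum(0.5, config.start_distance_m
                            - config.walk_speed_mps * t_walk))
    scale = config.focal_px / Z                      # px per metre

    blackout = int(np.argmax(Z <= config.blackout_distance_m))
    if Z[blackout] > config.blackout_distance_m:     # never that close
        blackout = T

    phase0 = rng.uniform(0, 2 * np.pi)
    sides = {"L": -1.0, "R": +1.0}
    angles: Dict[str, np.ndarray] = {}
    body = np.empty((T, len(LANDMARKS), 2))          # metres, body frame, y down
    sw, hw = config.shoulder_width_m / 2, config.hip_width_m / 2
    shoulder_pt = {"L": np.array([-sw, 0.0]), "R": np.array([+sw, 0.0])}
    hip_pt = {"L": np.array([-hw, config.trunk_length_m]),
              "R": np.array([+hw, config.trunk_length_m])}

    lateral_sway = 0.015 * np.sin(2 * np.pi * config.stride_hz * np.maximum(t_walk, 0))
    for side, lat in sides.items():
        affected = side == affected_side and severity > 0
        osc_phase = phase0 if side == "L" else phase0 + np.pi  # arms in antiphase
        sho_deg, elb_deg = _arm_schedule(config, severity, affected, t_walk, osc_phase)
        angles[f"shoulder_{side}"] = sho_deg
        angles[f"elbow_{side}"] = elb_deg

        sho = shoulder_pt[side][None, :] + np.column_stack([lateral_sway, np.zeros(T)])
        theta = np.radians(sho_deg)
        upper_dir = np.column_stack([np.sin(theta) * lat, np.cos(theta)])
        elb = sho + config.upper_arm_m * upper_dir
        bend = (180.0 - elb_deg) * (-lat)            # flex across the body
        cb, sb = np.cos(np.radians(bend)), np.sin(np.radians(bend))
        fore_dir = np.column_stack([cb * upper_dir[:, 0] - sb * upper_dir[:, 1],
                                    sb * upper_dir[:, 0] + cb * upper_dir[:, 1]])
        wri = elb + config.forearm_m * fore_dir

        i = LANDMARKS.index
        body[:, i(f"{side}_shoulder")] = sho
        body[:, i(f"{side}_elbow")] = elb
        body[:, i(f"{side}_wrist")] = wri
        body[:, i(f"{side}_hip")] = (hip_pt[side][None, :]
                                     + np.column_stack([lateral_sway, np.zeros(T)]))

    center = np.array([config.image_width / 2.0, config.image_height / 2.0])
    offset = np.array([0.0, config.trunk_length_m / 2.0])
    xy = center[None, None, :] + scale[:, None, None] * (body - offset[None, None, :])
    xy += rng.normal(0.0, config.jitter_px, xy.shape)

    likelihood = rng.uniform(config.likelihood_floor, 0.999, (T, len(LANDMARKS)))
    # isolated single-frame dropouts, never two in a row before the blackout
    drop = rng.random((T, len(LANDMARKS))) < config.isolated_dropout_p
    for j in range(len(LANDMARKS)):
        last = -10
        for f in np.flatnonzero(drop[:, j]):
            if f >= blackout - 1 or f - last < 3:
                continue
            likelihood[f, j] = rng.uniform(0.0, 0.3)
            last = f
    # permanent loss: wrists leave the frame first, then everything
    if blackout < T:
        wrist_cols = [LANDMARKS.index("L_wrist"), LANDMARKS.index("R_wrist")]
        likelihood[blackout:, wrist_cols] = rng.uniform(0.0, 0.2,
                                                        (T - blackout, 2))
        late = min(T, blackout + int(0.5 * fps))
        likelihood[late:, :] = rng.uniform(0.0, 0.2, (T - late, len(LANDMARKS)))

    trial_id = f"{participant_id}_t{trial}"
    trace = LandmarkTrace(
        trial_id=trial_id, participant_id=participant_id, group=group,
        xy=xy, likelihood=likelihood, image_width=config.image_width,
        image_height=config.image_height, fps=fps,
    )
    truth = TrialTruth(
        trial_id=trial_id, participant_id=participant_id, group=group,
        severity=severity, affected_side=affected_side, onset_frame=prefix,
        blackout_frame=blackout, n_frames=T, angles=angles,
    )
    return trace, truth


def simulate_ratings(
    severity: int, config: SynthConfig, seed: int
) -> Tuple[List[int], int]:
    """Scores from ``n_assessors`` simulated raters and their median.

    Each assessor reports round(severity + N(0, rater_sd)) clipped to 0..4.
    """
    if severity not in range(5):
        raise ValueError(f"severity must be in 0..4, got {severity}")
    rng = np.random.default_rng(seed)
    noisy = severity + rng.normal(0.0, config.rater_sd, config.n_assessors)
    scores = np.clip(np.rint(noisy), 0, 4).astype(int).tolist()
    return scores, int(np.median(scores))


def generate_cohort(
    config: SynthConfig, outdir: Optional[str | Path] = None
) -> Cohort:
    """Simulate a full cohort of traces, ratings and ground truth.

    Affected participants receive a severity drawn from
    ``config.severity_probs`` and a random affected side; healthy controls
    have severity 0.  All affected-group trials are rated; only one trial
    from each of the first ``n_rated_hc`` controls is rated, mirroring the
    practice of scoring just a handful of control videos to avoid flooding
    the label distribution with zeros.  Two runs with the same master seed
    produce byte-identical outputs.
    """
    ss = np.random.SeedSequence(config.master_seed)
    top_rng = np.random.default_rng(ss.spawn(1)[0])
    participants = ([(f"ABI{i + 1:02d}", "ABI") for i in range(config.n_abi)]
                    + [(f"HC{i + 1:02d}", "HC") for i in range(config.n_hc)])
    severities = {}
    sides = {}
    for pid, group in participants:
        if group == "ABI":
            severities[pid] = int(top_rng.choice(5, p=list(config.severity_probs)))
            sides[pid] = "L" if top_rng.random() < 0.5 else "R"
        else:
            severities[pid] = 0
            sides[pid] = "L"

    traces: List[LandmarkTrace] = []
    truth_rows = []
    rating_rows = []
    seeds: Dict[str, int] = {}
    rated_hc = {pid for pid, g in participants if g == "HC"}
    rated_hc = set(sorted(rated_hc)[: config.n_rated_hc])

    counter = 0
    for pid, group in participants:
        for trial in range(1, config.trials_per_participant + 1):
            counter += 1
            tseed = int(np.random.SeedSequence(
                [config.master_seed, counter]).generate_state(1)[0] % (2**31))
            trace, truth = simulate_trial(
                config, pid, trial, tseed, severities[pid], sides[pid], group)
            traces.append(trace)
            seeds[trace.trial_id] = tseed
            truth_rows.append({
                "trial_id": truth.trial_id, "participant_id": pid, "group": group,
                "severity": truth.severity, "affected_side": truth.affected_side,
                "onset_frame": truth.onset_frame,
                "blackout_frame": truth.blackout_frame, "n_frames": truth.n_frames,
            })
            rate = group == "ABI" or (pid in rated_hc and trial == 1)
            if rate:
                rseed = (tseed + 7919) % (2**31)
                scores, _ = simulate_ratings(severities[pid], config, rseed)
                for a, s in enumerate(scores, start=1):
                    rating_rows.append({"trial_id": trace.trial_id,
                                        "participant_id": pid,
                                        "assessor_id": f"A{a}", "score": s})

    ratings = pd.DataFrame(rating_rows)
    truth = pd.DataFrame(truth_rows)
    manifest = {"config": config_dict(config), "trial_seeds": seeds,
                "n_traces": len(traces), "n_rated_trials": ratings["trial_id"].nunique()}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        posedir = outdir / "pose"
        posedir.mkdir(exist_ok=True)
        for tr in traces:
            write_pose_csv(tr, posedir / f"{tr.trial_id}.csv")
        write_ratings(ratings, outdir / "ratings.csv")
        truth.to_csv(outdir / "truth.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
    return Cohort(traces=traces, ratings=ratings, truth=truth, manifest=manifest)
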