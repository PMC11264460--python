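"""Frontal-plane elbow and shoulder angles from 2D landmarks.

All angles are unsigned, computed as the arccos of the normalised dot
product between two segment vectors, and therefore lie in [0, 180] degrees.
A 2D frontal-plane projection cannot reliably disambiguate flexion
direction, so no sign convention is imposed.

Conventions (image coordinates, y increasing downward):

* elbow angle — at the elbow vertex, between the elbow->wrist and
  elbow->shoulder vectors; 180 deg = fully extended arm.
* trunk axis — unit vector from the shoulder midpoint toward the hip
  midpoint, i.e. the line running approximately through the sternum and
  sacrum, pointing inferiorly; recomputed every frame.
* shoulder angle — between the shoulder->elbow vector and the trunk axis;
  0 deg = arm hanging parallel to the trunk, 90 deg = arm horizontal
  (a frontal-plane abduction proxy).

Both constructions are invariant to translation and uniform scaling of the
image coordinates, so they do not depend on the subject's distance from the
camera; mirroring the image left-right swaps the left and right series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .landmark_io import LANDMARK_INDEX, LandmarkTrace

logger = logging.getLogger(__name__)

ANGLE_COLUMNS = ("elbow_L", "elbow_R", "shoulder_L", "shoulder_R")


class AngleError(ValueError):
    """Raised when angle computation is impossible for a whole trace."""


@dataclass
class AngleTraces:
    """Aligned per-frame angle series (degrees) for both limbs."""

    trial_id: str
    participant_id: str
    frame_index: np.ndarray
    elbow_L: np.ndarray
    elbow_R: np.ndarray
    shoulder_L: np.ndarray
    shoulder_R: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.frame_index)
        for name in ANGLE_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise AngleError(f"{name} misaligned with frame_index")
            if arr.size and (np.any(~np.isfinite(arr)) or arr.min() < 0 or arr.max() > 180):
                raise AngleError(f"{name} contains values outside [0, 180]")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def series(self, name: str) -> np.ndarray:
        if name not in ANGLE_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame_index": self.frame_index,
                             **{c: getattr(self, c) for c in ANGLE_COLUMNS}})

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.4f")
        return path


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle(s) between vectors, degrees in [0, 180]; NaN where degenerate."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(u * v, axis=-1) / denom
    cosang = np.where(denom > 0, cosang, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def elbow_angle(wrist, elbow, shoulder) -> float:
    """Angle at the elbow between elbow->wrist and elbow->shoulder, degrees.

    180 = fully extended (wrist and shoulder collinear on opposite sides of
    the elbow).  Raises :class:`AngleError` on a zero-length segment.
    """
    wrist, elbow, shoulder = (np.asarray(p, dtype=float) for p in (wrist, elbow, shoulder))
    ang = float(_angle_deg(wrist - elbow, shoulder - elbow))
    if not np.isfinite(ang):
        raise AngleError("undefined elbow angle: zero-length segment")
    return ang


def trunk_axis(hips, shoulders) -> np.ndarray:
    """Unit vector from the shoulder midpoint toward the hip midpoint.

    Points inferiorly under the image convention (y down).  ``hips`` and
    ``shoulders`` are (left, right) point pairs.
    """
    hip_mid = np.mean(np.asarray(hips, dtype=float), axis=0)
    sho_mid = np.mean(np.asarray(shoulders, dtype=float), axis=0)
    v = hip_mid - sho_mid
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise AngleError("undefined trunk axis: coincident midpoints")
    return v / n


def shoulder_angle(elbow, shoulder, axis) -> float:
    """Angle between shoulder->elbow and the trunk axis, degrees in [0, 180]."""
    elbow, shoulder = np.asarray(elbow, dtype=float), np.asarray(shoulder, dtype=float)
    ang = float(_angle_deg(elbow - shoulder, np.asarray(axis, dtype=float)))
    if not np.isfinite(ang):
        raise AngleError("undefined shoulder angle: zero-length upper-arm segment")
    return ang


def compute_angle_traces(trace: LandmarkTrace, min_valid_frames: int = 20) -> AngleTraces:
    """Per-frame elbow and shoulder angles for both limbs.

    Frames where any of the four angles is undefined (non-finite landmark or
    zero-length segment) are dropped from all four series jointly so the
    series stay aligned.  Angle series are returned unfiltered.
    """
    idx = LANDMARK_INDEX
    P = trace.xy  # (T, 8, 2)
    sho_L, sho_R = P[:, idx["L_shoulder"]], P[:, idx["R_shoulder"]]
    elb_L, elb_R = P[:, idx["L_elbow"]], P[:, idx["R_elbow"]]
    wri_L, wri_R = P[:, idx["L_wrist"]], P[:, idx["R_wrist"]]
    hip_L, hip_R = P[:, idx["L_hip"]], P[:, idx["R_hip"]]

    axis = (hip_L + hip_R) / 2 - (sho_L + sho_R) / 2
    with np.errstate(invalid="ignore"):
        angles = np.column_stack([
            _angle_deg(wri_L - elb_L, sho_L - elb_L),
            _angle_deg(wri_R - elb_R, sho_R - elb_R),
            _angle_deg(elb_L - sho_L, axis),
            _angle_deg(elb_R - sho_R, axis),
        ])
    valid = np.isfinite(angles).all(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("%s: dropped %d frame(s) with undefined angles",
                    trace.trial_id, n_dropped)
    if valid.sum() < min_valid_frames:
        raise AngleError(
            f"{trace.trial_id}: only {int(valid.sum())} valid frames "
            f"(< {min_valid_frames})")
    return AngleTraces(
        trial_id=trace.trial_id, participant_id=trace.participant_id,
        frame_index=trace.frame_index[valid],
        elbow_L=angles[valid, 0], elbow_R=angles[valid, 1],
        shoulder_L=angles[valid, 2], shoulder_R=angles[valid, 3],
    )
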