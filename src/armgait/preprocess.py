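"""Gait-segment trimming and landmark smoothing.

A recorded trial starts with the subject standing still and ends with the
subject too close to the camera, where landmarks leave the frame.  Both ends
are trimmed automatically:

* the walking onset is the first frame at which the pixel distance between
  the shoulder pair or the hip pair rises above its standing baseline — the
  body image grows as the subject approaches a front-facing camera;
* the end is the first frame of the earliest run of more than two
  consecutive frames in which any landmark is lost (low likelihood or
  non-finite coordinates).

Retained landmark coordinate series are three-point median filtered to
suppress single-frame estimation spikes.  Joint-angle series computed later
are never filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .config import TrimConfig
from .landmark_io import LANDMARK_INDEX, LandmarkTrace

logger = logging.getLogger(__name__)


class TrimError(ValueError):
    """Raised when no usable walking segment can be extracted."""


@dataclass(frozen=True)
class TrimResult:
    start_frame: int          # inclusive
    end_frame: int            # exclusive
    reason_start: str         # "distance_rise" | "trace_begin"
    reason_end: str           # "landmark_lost" | "trace_end"

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise TrimError(
                f"invalid trim window [{self.start_frame}, {self.end_frame})")


def lost_mask(trace: LandmarkTrace, likelihood_threshold: float) -> np.ndarray:
    """(T, 8) boolean mask: landmark lost at frame (low likelihood or non-finite)."""
    nonfinite = ~np.isfinite(trace.xy).all(axis=2)
    low = ~(trace.likelihood >= likelihood_threshold)  # NaN likelihood counts as lost
    return nonfinite | low


_MONITORED_PAIRS = (("L_shoulder", "R_shoulder"), ("L_hip", "R_hip"))


def _monitored_distances(trace: LandmarkTrace) -> np.ndarray:
    """(T, 2) per-frame shoulder width and hip width in pixels."""
    out = np.empty((trace.n_frames, len(_MONITORED_PAIRS)))
    for j, (a, b) in enumerate(_MONITORED_PAIRS):
        d = trace.xy[:, LANDMARK_INDEX[a], :] - trace.xy[:, LANDMARK_INDEX[b], :]
        out[:, j] = np.hypot(d[:, 0], d[:, 1])
    return out


def detect_walk_start(trace: LandmarkTrace, config: TrimConfig | None = None) -> int:
    """First frame at which a monitored body width exceeds its baseline.

    The baseline is the median width over the first ``baseline_window``
    frames; the onset is the first frame where any monitored width exceeds
    baseline * (1 + rise_fraction) for ``confirm_frames`` consecutive frames.
    Returns 0 if the condition already holds at the start of the trace.
    """
    config = config or TrimConfig()
    dist = _monitored_distances(trace)
    B = min(config.baseline_window, trace.n_frames)
    m = max(1, config.smooth_window) | 1  # odd window
    smoothed = np.column_stack([
        ndimage.median_filter(dist[:, j], size=m, mode="nearest")
        for j in range(dist.shape[1])
    ])
    baseline = np.nanmedian(smoothed[:B], axis=0)
    # jitter guard: per-frame noise scale from the standing baseline, scaled
    # down by the median-filter attenuation; exactly zero for clean input
    mad = np.nanmedian(np.abs(dist[:B] - np.nanmedian(dist[:B], axis=0)), axis=0)
    sigma = 1.4826 * mad * 1.25 / np.sqrt(m)
    threshold = baseline * (1.0 + config.rise_fraction) + config.noise_guard_mads * sigma
    risen = np.any(smoothed > threshold, axis=1)
    risen = np.where(np.isfinite(smoothed).all(axis=1), risen, False)

    C = max(1, config.confirm_frames)
    run = 0
    for t, flag in enumerate(risen):
        run = run + 1 if flag else 0
        if run >= C:
            return t - C + 1
    if config.fallback_start_at_zero:
        logger.warning("%s: no walking onset detected; starting at frame 0",
                       trace.trial_id)
        return 0
    raise TrimError(f"{trace.trial_id}: no walking onset detected")


def detect_walk_end(trace: LandmarkTrace, config: TrimConfig | None = None) -> int:
    """Exclusive end index: first frame of the earliest run of >2 consecutive
    lost frames for any landmark; T if no landmark is ever lost that long."""
    config = config or TrimConfig()
    lost = lost_mask(trace, config.likelihood_threshold)
    T = trace.n_frames
    end = T
    for i in range(lost.shape[1]):
        run_start = None
        run_len = 0
        for t in range(T):
            if lost[t, i]:
                if run_len == 0:
                    run_start = t
                run_len += 1
                if run_len > 2:  # strictly more than two consecutive frames
                    end = min(end, run_start)
                    break
            else:
                run_len = 0
    return end


def median_filter3(series: np.ndarray) -> np.ndarray:
    """Three-point running median with edge replication.

    Interior samples become the median of (previous, self, next); the first
    and last samples use a replicated edge, which leaves them unchanged for
    a 3-point window.  Output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("median_filter3 expects a 1-D series")
    if x.size == 0:
        raise ValueError("median_filter3 requires length >= 1")
    if x.size < 3:
        return x.copy()
    padded = np.concatenate(([x[0]], x, [x[-1]]))
    stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
    return np.median(stacked, axis=0)


def preprocess_trace(
    trace: LandmarkTrace, config: TrimConfig | None = None
) -> Tuple[LandmarkTrace, TrimResult]:
    """Trim to the walking segment and median-filter landmark coordinates.

    Composes :func:`detect_walk_start` and :func:`detect_walk_end`, slices
    the trace to [start, end), then applies :func:`median_filter3` to every
    landmark x and y series.  Likelihood series are not filtered, and joint
    angles computed downstream are never filtered.
    """
    config = config or TrimConfig()
    end = detect_walk_end(trace, config)
    if end == 0:
        raise TrimError(f"{trace.trial_id}: landmarks lost from the first frame")
    start = detect_walk_start(trace.sliced(0, end), config)
    reason_start = "trace_begin" if start == 0 else "distance_rise"
    reason_end = "landmark_lost" if end < trace.n_frames else "trace_end"
    if end - start < config.min_retained_frames:
        raise TrimError(
            f"{trace.trial_id}: retained segment [{start}, {end}) shorter than "
            f"minimum {config.min_retained_frames} frames")
    out = trace.sliced(start, end)
    for i in range(out.xy.shape[1]):
        out.xy[:, i, 0] = median_filter3(out.xy[:, i, 0])
        out.xy[:, i, 1] = median_filter3(out.xy[:, i, 1])
    return out, TrimResult(start, end, reason_start, reason_end)
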