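"""Reading and writing landmark traces and assessor-rating tables.

Two on-disk dialects are supported for landmark time series:

* the pose-estimation tool's native CSV with three header rows
  (``scorer`` / ``bodyparts`` / ``coords``) and one ``x, y, likelihood``
  triple per bodypart per frame row;
* a flat CSV with one column per landmark coordinate
  (``L_shoulder_x, L_shoulder_y, L_shoulder_likelihood, ...``), where the
  likelihood columns may be omitted.

Ratings tables are plain CSVs with columns
``trial_id, participant_id, assessor_id, score``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import IOConfig

logger = logging.getLogger(__name__)

#: Canonical landmark order used throughout the package.
LANDMARKS = (
    "L_shoulder", "R_shoulder",
    "L_elbow", "R_elbow",
    "L_wrist", "R_wrist",
    "L_hip", "R_hip",
)
LANDMARK_INDEX = {name: i for i, name in enumerate(LANDMARKS)}

COORD_PRECISION = 6  # decimals written; round-trip identity holds at this precision


class LandmarkError(ValueError):
    """Raised for structurally invalid landmark files or traces."""


class RatingsError(ValueError):
    """Raised for invalid ratings tables."""


@dataclass
class LandmarkTrace:
    """Per-trial time series of 8 landmark records.

    ``xy`` has shape (T, 8, 2) in image pixels (origin top-left, y down);
    ``likelihood`` has shape (T, 8) with values in [0, 1].  Landmark order
    follows :data:`LANDMARKS`.
    """

    trial_id: str
    participant_id: str
    group: str  # "ABI" or "HC"
    xy: np.ndarray
    likelihood: np.ndarray
    image_width: int = 1920
    image_height: int = 1080
    fps: float = 30.0
    frame_index: np.ndarray = field(default=None)  # original frame numbers

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (len(LANDMARKS), 2):
            raise LandmarkError(f"xy must have shape (T, 8, 2), got {self.xy.shape}")
        if self.xy.shape[0] < 1:
            raise LandmarkError("a trace must contain at least one frame")
        if self.likelihood.shape != self.xy.shape[:2]:
            raise LandmarkError("likelihood must have shape (T, 8)")
        finite = np.isfinite(self.likelihood)
        if np.any((self.likelihood[finite] < 0) | (self.likelihood[finite] > 1)):
            raise LandmarkError("likelihood values must lie in [0, 1]")
        if self.group not in ("ABI", "HC"):
            raise LandmarkError(f"group must be 'ABI' or 'HC', got {self.group!r}")
        if self.frame_index is None:
            self.frame_index = np.arange(self.xy.shape[0])
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)
            if self.frame_index.shape != (self.xy.shape[0],):
                raise LandmarkError("frame_index length must equal T")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def landmark(self, name: str) -> np.ndarray:
        """(T, 2) coordinate series for one landmark."""
        return self.xy[:, LANDMARK_INDEX[name], :]

    def sliced(self, start: int, stop: int) -> "LandmarkTrace":
        """Contiguous frame slice [start, stop) preserving metadata."""
        return LandmarkTrace(
            trial_id=self.trial_id, participant_id=self.participant_id,
            group=self.group, xy=self.xy[start:stop].copy(),
            likelihood=self.likelihood[start:stop].copy(),
            image_width=self.image_width, image_height=self.image_height,
            fps=self.fps, frame_index=self.frame_index[start:stop].copy(),
        )

    def equals(self, other: "LandmarkTrace", decimals: int = COORD_PRECISION) -> bool:
        """Equality of coordinates/likelihoods at the stated decimal precision."""
        a = np.round(self.xy, decimals)
        b = np.round(other.xy, decimals)
        return (
            self.xy.shape == other.xy.shape
            and np.array_equal(a, b, equal_nan=True)
            and np.array_equal(np.round(self.likelihood, decimals),
                               np.round(other.likelihood, decimals), equal_nan=True)
            and np.array_equal(self.frame_index, other.frame_index)
        )


def _canonical_name(raw: str, aliases: dict) -> Optional[str]:
    if raw in aliases:
        return aliases[raw]
    return aliases.get(raw.strip())


def read_pose_csv(
    path: str | Path,
    config: IOConfig | None = None,
    *,
    trial_id: str | None = None,
    participant_id: str | None = None,
    group: str = "ABI",
    image_width: int = 1920,
    image_height: int = 1080,
    fps: float = 30.0,
) -> LandmarkTrace:
    """Read a three-header-row pose CSV (scorer / bodyparts / coords).

    Bodypart names are mapped through ``config.aliases``; a missing required
    landmark or a malformed header is a hard error.  Extra bodyparts are
    ignored with a warning.  Trial/participant identifiers default to the
    file stem.
    """
    path = Path(path)
    config = config or IOConfig()
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise LandmarkError(f"{path}: malformed pose CSV header: {exc}") from exc
    if df.columns.nlevels != 3:
        raise LandmarkError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")

    found: dict[str, dict[str, np.ndarray]] = {}
    extras = set()
    for scorer, bodypart, coord in df.columns:
        name = _canonical_name(str(bodypart), config.aliases)
        if name is None:
            extras.add(str(bodypart))
            continue
        coord = str(coord).strip().lower()
        if coord not in ("x", "y", "likelihood"):
            raise LandmarkError(f"{path}: unexpected coords header {coord!r} for {bodypart!r}")
        found.setdefault(name, {})[coord] = df[(scorer, bodypart, coord)].to_numpy(dtype=float)
    if extras:
        logger.warning("%s: ignoring unknown bodypart(s) %s", path, sorted(extras))

    missing = [lm for lm in LANDMARKS if lm not in found]
    if missing:
        raise LandmarkError(f"{path}: landmark {missing[0]} absent")

    T = len(df)
    xy = np.empty((T, len(LANDMARKS), 2))
    lik = np.empty((T, len(LANDMARKS)))
    for i, lm in enumerate(LANDMARKS):
        cols = found[lm]
        if "x" not in cols or "y" not in cols:
            raise LandmarkError(f"{path}: landmark {lm} lacks x/y columns")
        xy[:, i, 0] = cols["x"]
        xy[:, i, 1] = cols["y"]
        if "likelihood" in cols:
            lik[:, i] = cols["likelihood"]
        else:
            lik[:, i] = config.likelihood_default
            logger.info("%s: no likelihood column for %s; assuming %.2f",
                        path, lm, config.likelihood_default)
    return LandmarkTrace(
        trial_id=trial_id or path.stem, participant_id=participant_id or path.stem,
        group=group, xy=xy, likelihood=lik, image_width=image_width,
        image_height=image_height, fps=fps,
        frame_index=df.index.to_numpy(dtype=int),
    )


def write_pose_csv(trace: LandmarkTrace, path: str | Path, scorer: str = "armgait") -> Path:
    """Write a trace in the three-header-row pose CSV dialect."""
    path = Path(path)
    cols = pd.MultiIndex.from_tuples(
        [(scorer, lm, c) for lm in LANDMARKS for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    T = trace.n_frames
    data = np.empty((T, len(LANDMARKS) * 3))
    for i in range(len(LANDMARKS)):
        data[:, 3 * i] = trace.xy[:, i, 0]
        data[:, 3 * i + 1] = trace.xy[:, i, 1]
        data[:, 3 * i + 2] = trace.likelihood[:, i]
    df = pd.DataFrame(np.round(data, COORD_PRECISION), columns=cols,
                      index=pd.Index(trace.frame_index))
    df.to_csv(path, float_format=f"%.{COORD_PRECISION}f")
    return path


def read_flat_csv(
    path: str | Path,
    config: IOConfig | None = None,
    **meta,
) -> LandmarkTrace:
    """Read the flat dialect: one column per landmark coordinate.

    Expected columns ``<landmark>_x``, ``<landmark>_y`` and optionally
    ``<landmark>_likelihood`` (missing likelihoods default to
    ``config.likelihood_default``).  An optional ``frame`` column carries
    original frame numbers.
    """
    path = Path(path)
    config = config or IOConfig()
    df = pd.read_csv(path)
    T = len(df)
    xy = np.empty((T, len(LANDMARKS), 2))
    lik = np.empty((T, len(LANDMARKS)))
    for i, lm in enumerate(LANDMARKS):
        for j, c in enumerate(("x", "y")):
            col = f"{lm}_{c}"
            if col not in df.columns:
                raise LandmarkError(f"{path}: landmark {lm} absent (no column {col})")
            xy[:, i, j] = df[col].to_numpy(dtype=float)
        lcol = f"{lm}_likelihood"
        lik[:, i] = (df[lcol].to_numpy(dtype=float) if lcol in df.columns
                     else config.likelihood_default)
    frame_index = df["frame"].to_numpy(dtype=int) if "frame" in df.columns else None
    meta.setdefault("trial_id", path.stem)
    meta.setdefault("participant_id", path.stem)
    meta.setdefault("group", "ABI")
    return LandmarkTrace(xy=xy, likelihood=lik, frame_index=frame_index, **meta)


def write_flat_csv(trace: LandmarkTrace, path: str | Path) -> Path:
    """Write a trace in the flat one-column-per-coordinate dialect."""
    path = Path(path)
    out = {"frame": trace.frame_index}
    for i, lm in enumerate(LANDMARKS):
        out[f"{lm}_x"] = np.round(trace.xy[:, i, 0], COORD_PRECISION)
        out[f"{lm}_y"] = np.round(trace.xy[:, i, 1], COORD_PRECISION)
        out[f"{lm}_likelihood"] = np.round(trace.likelihood[:, i], COORD_PRECISION)
    pd.DataFrame(out).to_csv(path, index=False, float_format=f"%.{COORD_PRECISION}f")
    return path


RATING_COLUMNS = ("trial_id", "participant_id", "assessor_id", "score")


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a ratings table: integer scores 0-4, unique (trial, assessor)."""
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsError(f"ratings table missing column(s) {missing}")
    df = df.loc[:, list(RATING_COLUMNS)].copy()
    scores = df["score"]
    try:
        as_int = scores.astype(float)
        noninteger = (as_int % 1 != 0) | ~np.isfinite(as_int)
    except (TypeError, ValueError) as exc:
        raise RatingsError(f"non-numeric score: {exc}") from exc
    if noninteger.any():
        row = int(np.argmax(noninteger.to_numpy()))
        raise RatingsError(f"non-integer score at row {row}: {scores.iloc[row]!r}")
    df["score"] = as_int.astype(int)
    out_of_range = (df["score"] < 0) | (df["score"] > 4)
    if out_of_range.any():
        row = int(np.argmax(out_of_range.to_numpy()))
        raise RatingsError(f"score out of range [0, 4] at row {row}: {df['score'].iloc[row]}")
    dup = df.duplicated(subset=["trial_id", "assessor_id"])
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise RatingsError(f"duplicate (trial_id, assessor_id) at row {row}: "
                           f"{df[['trial_id', 'assessor_id']].iloc[row].tolist()}")
    return df


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read and validate a ratings CSV (trial_id, participant_id, assessor_id, score)."""
    return validate_ratings(pd.read_csv(Path(path)))


def write_ratings(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_ratings(df).to_csv(path, index=False)
    return path
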