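"""Per-trial summary features and training labels.

Each trial's four angle series (left/right elbow, left/right shoulder) are
reduced to six summary statistics each — maximum, minimum, mean, standard
deviation, skewness and kurtosis — giving a 24-dimensional feature vector.
The training label is the median of the assessors' ordinal 0-4 scores; the
median of an odd number of integers is itself an integer, which keeps the
label ordinal.

Estimator conventions (documented so ports to other stacks match): standard
deviation uses the n-1 (sample) denominator, skewness is the Fisher third
standardised moment and kurtosis is excess kurtosis (normal = 0), both with
biased (moment) estimators.  A constant series has sd = 0 and, by
convention, skew = kurtosis = 0.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import ANGLE_COLUMNS, AngleTraces
from .landmark_io import validate_ratings

logger = logging.getLogger(__name__)

SUMMARY_STATS = ("max", "min", "mean", "sd", "skew", "kurt")

#: Fixed feature-column order (stable feature-importance reporting).
FEATURE_COLUMNS = tuple(
    f"{joint}_{stat}" for joint in ANGLE_COLUMNS for stat in SUMMARY_STATS
)
LABEL_COLUMN = "median_score"
ID_COLUMNS = ("trial_id", "participant_id")


class TraceSummary(NamedTuple):
    max: float
    min: float
    mean: float
    sd: float
    skew: float
    kurt: float


def summarize_trace(series, min_length: int = 1) -> TraceSummary:
    """Six summary statistics of one angle series.

    Returns (max, min, mean, sample sd, Fisher skew, excess kurtosis);
    a constant series yields sd = skew = kurt = 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty series")
    if x.size < min_length:
        raise ValueError(f"series length {x.size} below minimum {min_length}")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return TraceSummary(float(np.max(x)), float(np.min(x)), float(np.mean(x)),
                        sd, skew, kurt)


def median_label(scores: Iterable[int]) -> int:
    """Median assessor score as an integer label.

    For an odd number of assessors this is the middle value and already an
    integer.  With an even count a half-integer median is rounded half down
    (toward the lower severity) with a warning.
    """
    vals = sorted(int(s) for s in scores)
    if not vals:
        raise ValueError("no scores to take a median of")
    med = float(np.median(vals))
    if med != int(med):
        logger.warning("non-integer median %.1f from even assessor count; "
                       "rounding half down", med)
        return int(math.floor(med))
    return int(med)


def feature_row(angles: AngleTraces) -> dict:
    """24 named features for one trial's angle traces."""
    row: dict = {"trial_id": angles.trial_id, "participant_id": angles.participant_id}
    for joint in ANGLE_COLUMNS:
        summ = summarize_trace(angles.series(joint))
        for stat in SUMMARY_STATS:
            row[f"{joint}_{stat}"] = getattr(summ, stat)
    return row


def build_feature_table(
    traces: Iterable[AngleTraces], ratings: pd.DataFrame
) -> pd.DataFrame:
    """One row per trial: identifiers, 24 features and the median label.

    Trials without any rating are excluded with a warning.  Column order is
    fixed: trial_id, participant_id, the 24 features in
    :data:`FEATURE_COLUMNS` order, then ``median_score``.
    """
    ratings = validate_ratings(ratings)
    by_trial = ratings.groupby("trial_id")["score"].apply(list).to_dict()
    rows = []
    for tr in traces:
        scores = by_trial.get(tr.trial_id)
        if not scores:
            logger.warning("trial %s has no ratings; excluded", tr.trial_id)
            continue
        row = feature_row(tr)
        row[LABEL_COLUMN] = median_label(scores)
        rows.append(row)
    if not rows:
        raise ValueError("no rated trials: feature table would be empty")
    cols = list(ID_COLUMNS) + list(FEATURE_COLUMNS) + [LABEL_COLUMN]
    return pd.DataFrame(rows, columns=cols)
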