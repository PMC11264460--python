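"""Shared fixtures: synthetic traces and cohorts built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from armgait.config import ModelConfig, SynthConfig
from armgait.features import build_feature_table
from armgait.kinematics import compute_angle_traces
from armgait.landmark_io import LANDMARKS, LandmarkTrace
from armgait.preprocess import preprocess_trace
from armgait.synth_gait import generate_cohort


def make_trace(xy, likelihood=None, **kw):
    """LandmarkTrace from an (T, 8, 2) array with defaults filled in."""
    xy = np.asarray(xy, dtype=float)
    if likelihood is None:
        likelihood = np.ones(xy.shape[:2])
    kw.setdefault("trial_id", "trial")
    kw.setdefault("participant_id", "p")
    kw.setdefault("group", "ABI")
    return LandmarkTrace(xy=xy, likelihood=likelihood, **kw)


def standing_pose(T=40, width=100.0):
    """(T, 8, 2) static anatomical pose: arms hanging, elbows extended."""
    pose = {
        "L_shoulder": (-50, 0), "R_shoulder": (50, 0),
        "L_elbow": (-50, 60), "R_elbow": (50, 60),
        "L_wrist": (-50, 115), "R_wrist": (50, 115),
        "L_hip": (-30, 100), "R_hip": (30, 100),
    }
    xy = np.empty((T, len(LANDMARKS), 2))
    for i, lm in enumerate(LANDMARKS):
        xy[:, i] = np.array(pose[lm]) * (width / 100.0) + np.array([960, 400])
    return xy


@pytest.fixture(scope="session")
def small_cohort():
    """Small but fully structured cohort: 11 participants, 2 trials each."""
    return generate_cohort(SynthConfig(n_abi=8, n_hc=3, n_rated_hc=2, master_seed=3))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    angles = [compute_angle_traces(preprocess_trace(t)[0])
              for t in small_cohort.traces]
    return build_feature_table(angles, small_cohort.ratings)


@pytest.fixture(scope="session")
def fast_model_config():
    """Down-scaled hyperparameter grid so nested CV stays desk-fast."""
    return ModelConfig(random_seed=7, n_estimators_grid=(100,),
                       max_depth_grid=(None, 5), min_samples_leaf_grid=(1, 3))


@pytest.fixture(scope="session")
def cohort150():
    """Cohort with 150 rated trials and strong severity effects."""
    return generate_cohort(SynthConfig(n_abi=73, n_hc=4, n_rated_hc=4, master_seed=7))


@pytest.fixture(scope="session")
def table150(cohort150):
    angles = [compute_angle_traces(preprocess_trace(t)[0])
              for t in cohort150.traces]
    return build_feature_table(angles, cohort150.ratings)
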