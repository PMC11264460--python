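"""Configuration objects for every pipeline stage.

Each stage owns a small frozen-ish dataclass; :class:`PipelineConfig` nests
them and can be loaded from a single YAML file.  Unknown keys are rejected so
a typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Tuple

import yaml


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration values."""


@dataclass
class IOConfig:
    """Landmark-file reading options.

    ``aliases`` maps bodypart names found in pose-tool CSV headers onto the
    eight canonical landmark names; the defaults cover common conventions
    (``LSHO``/``left_shoulder``/... -> ``L_shoulder``).
    """

    likelihood_default: float = 1.0
    aliases: dict = field(default_factory=lambda: dict(_DEFAULT_ALIASES))


@dataclass
class TrimConfig:
    """Walk-onset / landmark-loss trimming parameters.

    likelihood_threshold: a landmark with per-frame likelihood below this (or
        non-finite coordinates) counts as lost.
    baseline_window: frames used to establish the baseline body-width scale.
    rise_fraction: relative rise of shoulder/hip pixel width over baseline
        that signals the subject is approaching the camera.
    confirm_frames: consecutive frames the rise must persist.
    smooth_window: running-median window (frames) applied to the monitored
        widths before onset detection; suppresses landmark jitter.
    noise_guard_mads: extra margin added to the rise threshold, in MAD-scaled
        units of the baseline-window jitter; zero for noise-free input.
    min_retained_frames: shortest usable walking segment.
    """

    likelihood_threshold: float = 0.6
    baseline_window: int = 30
    rise_fraction: float = 0.05
    confirm_frames: int = 3
    smooth_window: int = 11
    noise_guard_mads: float = 3.0
    min_retained_frames: int = 20
    fallback_start_at_zero: bool = False


@dataclass
class ModelConfig:
    """Nested cross-validation and random-forest settings."""

    outer_folds: int = 5
    inner_folds: int = 5
    n_estimators_grid: Tuple[int, ...] = (100, 300, 500)
    max_depth_grid: Tuple[Optional[int], ...] = (None, 5, 10)
    min_samples_leaf_grid: Tuple[int, ...] = (1, 3, 5)
    random_seed: int = 0
    grouping: str = "by_participant"  # or "by_trial"
    class_weight: Optional[str] = None  # e.g. "balanced"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigError("outer_folds and inner_folds must each be >= 2")
        if self.grouping not in ("by_participant", "by_trial"):
            raise ConfigError(f"unknown grouping {self.grouping!r}")
        if not (self.n_estimators_grid and self.max_depth_grid and self.min_samples_leaf_grid):
            raise ConfigError("hyperparameter grid must be non-empty")

    @property
    def param_grid(self) -> dict:
        return {
            "forest__n_estimators": list(self.n_estimators_grid),
            "forest__max_depth": list(self.max_depth_grid),
            "forest__min_samples_leaf": list(self.min_samples_leaf_grid),
        }


@dataclass
class SynthConfig:
    """Synthetic cohort generator settings.

    The defaults emulate the study conditions the pipeline was designed for:
    a subject walking down a 10 m walkway toward a fixed 1920x1080 camera,
    two recorded trials per participant, 42 affected participants and 34
    healthy controls, and three experienced assessors scoring each trial on
    the 0-4 ICF qualifiers scale.
    """

    n_abi: int = 42
    n_hc: int = 34
    trials_per_participant: int = 2
    n_rated_hc: int = 5          # only a handful of control videos are scored
    fps: float = 30.0
    image_width: int = 1920
    image_height: int = 1080
    focal_px: float = 1050.0     # typical 1080p RGB camera intrinsic
    stationary_s: float = 2.0    # pre-walk standing time
    walk_distance_m: float = 9.0 # approach from ~10 m to ~1 m of the camera
    start_distance_m: float = 10.0
    walk_speed_mps: float = 1.1  # self-selected comfortable pace
    # body geometry (metres)
    shoulder_width_m: float = 0.38
    hip_width_m: float = 0.30
    trunk_length_m: float = 0.50
    upper_arm_m: float = 0.30
    forearm_m: float = 0.26
    # arm model per severity step (degrees)
    swing_amplitude_deg: float = 8.0      # frontal-plane projected swing
    swing_reduction_per_severity: float = 0.22
    elbow_baseline_deg: float = 168.0
    elbow_flexion_per_severity: float = 11.0
    shoulder_baseline_deg: float = 4.0
    abduction_per_severity: float = 6.5
    stride_hz: float = 0.9
    # noise model
    jitter_px: float = 2.0       # landmark error comparable to a trained network
    isolated_dropout_p: float = 0.004
    likelihood_floor: float = 0.85
    blackout_distance_m: float = 1.6  # landmarks leave frame when this close
    # rater model
    n_assessors: int = 3
    rater_sd: float = 0.6        # moderate inter-rater reliability
    severity_probs: Tuple[float, ...] = (0.12, 0.22, 0.28, 0.23, 0.15)
    master_seed: int = 0

    def __post_init__(self) -> None:
        probs = tuple(self.severity_probs)
        if len(probs) != 5 or any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ConfigError("severity_probs must be 5 non-negative values summing to 1")
        if not 0 <= self.isolated_dropout_p <= 1:
            raise ConfigError("isolated_dropout_p must be in [0, 1]")


@dataclass
class ReportConfig:
    """Agreement-report options."""

    kappa_bootstrap: int = 2000
    kappa_se_method: str = "bootstrap"  # or "asymptotic"
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    trim: TrimConfig = field(default_factory=TrimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    report: ReportConfig = field(default_factory=ReportConfig)


_DEFAULT_ALIASES = {
    # canonical names map to themselves
    "L_shoulder": "L_shoulder", "R_shoulder": "R_shoulder",
    "L_elbow": "L_elbow", "R_elbow": "R_elbow",
    "L_wrist": "L_wrist", "R_wrist": "R_wrist",
    "L_hip": "L_hip", "R_hip": "R_hip",
    # common pose-tool spellings
    "left_shoulder": "L_shoulder", "right_shoulder": "R_shoulder",
    "left_elbow": "L_elbow", "right_elbow": "R_elbow",
    "left_wrist": "L_wrist", "right_wrist": "R_wrist",
    "left_hip": "L_hip", "right_hip": "R_hip",
    "LSHO": "L_shoulder", "RSHO": "R_shoulder",
    "LELB": "L_elbow", "RELB": "R_elbow",
    "LWRA": "L_wrist", "RWRA": "R_wrist",
    "LASI": "L_hip", "RASI": "R_hip",
}


def _build(cls, data: Mapping[str, Any], ctx: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {ctx!r}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(f.default, tuple):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    sections = {"io": IOConfig, "trim": TrimConfig, "model": ModelConfig,
                "synth": SynthConfig, "report": ReportConfig}
    unknown = set(raw) - set(sections)
    if unknown:
        raise ConfigError(f"unknown top-level section(s) {sorted(unknown)}")
    kwargs = {name: _build(cls, raw.get(name, {}) or {}, name)
              for name, cls in sections.items()}
    return PipelineConfig(**kwargs)


def config_dict(cfg) -> dict:
    """Dataclass tree -> plain dict (for manifests)."""
    return dataclasses.asdict(cfg)
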