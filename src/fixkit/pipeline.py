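"""Pipeline orchestration and configuration.

Stage order is fixed: Kalman smoothing -> OPTICS stabilization -> affine
normalization -> velocity/EAR segmentation -> per-bin features. Individual
preprocessing stages can be toggled off explicitly (never silently); the
normalization stage always runs because the segmenter's velocity units are
defined on normalized coordinates.

Configuration is a plain YAML mapping with sections ``kalman``, ``optics``,
``segment``, ``features``, ``sim``, ``stages`` plus top-level ``fps`` and
``pupil_mode``. Unknown keys are errors, so typos never pass silently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .affine import NormalizedPupilTrace, normalize_stream
from .errors import FixkitError, FormatError
from .features import compute_feature_table, extract_segments
from .io import DEFAULT_EYE_MAP, EyeLandmarkMap, LandmarkStream
from .kalman import KalmanConfig, smooth_stream
from .optics import OpticsConfig, stabilize_stream
from .segment import (
    DEFAULT_EAR_THRESHOLD,
    FixationVector,
    ThresholdSearchConfig,
    binocular_mean,
    ear_trace,
    estimate_threshold,
    moving_average,
    pupil_displacement,
    valid_mask,
)
from .simulate import GazeSimConfig

logger = logging.getLogger("fixkit")

__all__ = ["StageToggles", "PipelineConfig", "PipelineResult", "run_pipeline",
           "load_config"]


@dataclass(frozen=True)
class StageToggles:
    smooth: bool = True
    stabilize: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    fps: Optional[float] = None  # override; otherwise taken from the stream
    pupil_mode: str = "center"
    ear_threshold: float = DEFAULT_EAR_THRESHOLD
    bin_seconds: float = 3.0
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    segment: ThresholdSearchConfig = field(default_factory=ThresholdSearchConfig)
    sim: GazeSimConfig = field(default_factory=GazeSimConfig)
    stages: StageToggles = field(default_factory=StageToggles)


_SECTION_TYPES = {
    "kalman": KalmanConfig,
    "optics": OpticsConfig,
    "segment": ThresholdSearchConfig,
    "sim": GazeSimConfig,
    "stages": StageToggles,
}
_TOP_KEYS = {"fps", "pupil_mode", "ear_threshold", "bin_seconds"} | set(_SECTION_TYPES)


def _build_section(cls, data: Mapping[str, Any], section: str):
    if not isinstance(data, Mapping):
        raise FormatError(f"config section '{section}' must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown key(s) {sorted(unknown)} in config section '{section}'")
    fixed = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    try:
        return cls(**fixed)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid config section '{section}': {exc}") from exc


def config_from_dict(data: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a validated PipelineConfig; unknown keys are errors."""
    data = dict(data or {})
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise FormatError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs: Dict[str, Any] = {}
    for key in ("fps", "pupil_mode", "ear_threshold", "bin_seconds"):
        if key in data:
            kwargs[key] = data[key]
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            kwargs[section] = _build_section(cls, data[section], section)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; None loads defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"cannot parse config {path}: {exc}") from exc
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> Dict[str, Any]:
    """Normalized plain-dict form (round-trips through config_from_dict)."""
    return dataclasses.asdict(cfg)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    fixation: FixationVector
    trace: NormalizedPupilTrace
    velocity: np.ndarray  # smoothed binocular velocity, units/frame
    ear: np.ndarray  # (T, 2) left/right
    valid: np.ndarray
    segments: list
    intermediates: Dict[str, LandmarkStream] = field(default_factory=dict)


class StageError(FixkitError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(
    stream: LandmarkStream,
    cfg: PipelineConfig | None = None,
    eye_map: EyeLandmarkMap = DEFAULT_EYE_MAP,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Execute the full landmark-to-features pipeline on one stream."""
    cfg = cfg or PipelineConfig()
    if cfg.fps is not None and cfg.fps != stream.fps:
        stream = LandmarkStream(
            fps=cfg.fps,
            frame_index=stream.frame_index,
            landmark_ids=stream.landmark_ids,
            coords=stream.coords,
            confidence=stream.confidence,
        )
    fps = stream.fps
    stream.validate(min_frames=3)
    intermediates: Dict[str, LandmarkStream] = {}

    def _stage(name, fn, *args, **kwargs):
        logger.info("stage %s: start (T=%d)", name, stream.n_frames)
        try:
            return fn(*args, **kwargs)
        except FixkitError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(name, exc) from exc

    # EAR and validity are computed on the raw input: blinks must be judged
    # before temporal filters reshape the lid trajectory
    ear = _stage("ear", ear_trace, stream, eye_map)
    valid = _stage("valid_mask", valid_mask, stream, eye_map, cfg.ear_threshold)
    logger.info("valid frames: %d / %d", int(valid.sum()), stream.n_frames)

    current = stream
    if cfg.stages.smooth:
        current = _stage("kalman", smooth_stream, current, cfg.kalman)
        if keep_intermediates:
            intermediates["smoothed"] = current
    else:
        logger.info("stage kalman: skipped by config")
    if cfg.stages.stabilize:
        current = _stage("optics", stabilize_stream, current, cfg.optics)
        if keep_intermediates:
            intermediates["stabilized"] = current
    else:
        logger.info("stage optics: skipped by config")

    trace = _stage("affine", normalize_stream, current, eye_map, cfg.pupil_mode)
    # frames invalidated by blinks are removed from the normalized trace too
    trace.valid_left &= valid
    trace.valid_right &= valid
    trace.left[~trace.valid_left] = np.nan
    trace.right[~trace.valid_right] = np.nan

    d_left = moving_average(pupil_displacement(trace, "left"), fps=fps)
    d_right = moving_average(pupil_displacement(trace, "right"), fps=fps)
    velocity = binocular_mean(d_left, d_right)

    fixation = _stage("segment", estimate_threshold, velocity, valid, fps, cfg.segment)
    logger.info(
        "threshold %.6g converged=%s ratio=%.4f iterations=%d",
        fixation.threshold, fixation.converged, fixation.ratio, fixation.n_iter,
    )
    segments = extract_segments(fixation, fps)
    features = compute_feature_table(segments, fixation, fps, cfg.bin_seconds)
    return PipelineResult(
        features=features,
        fixation=fixation,
        trace=trace,
        velocity=velocity,
        ear=ear,
        valid=valid,
        segments=segments,
        intermediates=intermediates,
    )
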