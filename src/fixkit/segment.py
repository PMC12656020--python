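"""Velocity-based fixation segmentation with iterative threshold search.

The segmenter works on normalized pupil coordinates (units: eye-box widths
per frame). Per eye, frame-to-frame Euclidean displacement is computed
(aligned to the later frame; the first frame has undefined velocity),
smoothed with a centered moving average of half-width q = ceil(fps / 30),
and the two eyes are averaged. Blink frames — where either eye's aspect
ratio EAR = (|P2-P6| + |P3-P5|) / (2 |P1-P4|) falls below a threshold
(default 0.2) — are invalid: they break fixation runs and are excluded
from all ratios.

A frame belongs to a fixation when it lies inside a maximal run of valid
below-threshold frames at least ``min_fix_frames`` long (8 frames at
30 fps; generalized as max(2, round(fps * 8/30))). The fixation threshold
itself is not fixed a priori: it is chosen by bisection so that the
fraction of valid time classified as fixation hits a target ratio (default
0.90, the literature's long-run fixation share) within an absolute
tolerance (default 0.0025, i.e. +/-0.25 percentage points). The fixation
ratio is non-decreasing in the threshold, which makes bisection exact; if
the target is unattainable within ``itermax`` iterations the best
threshold found is returned flagged as non-converged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .io import DEFAULT_EYE_MAP, EyeLandmarkMap, LandmarkFrame, LandmarkStream
from .affine import NormalizedPupilTrace

__all__ = [
    "ThresholdSearchConfig",
    "FixationVector",
    "FixationSegmenter",
    "pupil_displacement",
    "moving_average",
    "binocular_mean",
    "compute_ear",
    "ear_trace",
    "valid_mask",
    "default_min_fix_frames",
    "fixation_runs",
    "fixation_ratio_at",
    "estimate_threshold",
]

DEFAULT_EAR_THRESHOLD = 0.2


@dataclass(frozen=True)
class ThresholdSearchConfig:
    target_ratio: float = 0.90
    tolerance: float = 0.0025  # absolute, on the ratio
    itermax: int = 100
    min_fix_frames: Optional[int] = None  # None -> max(2, round(fps * 8/30))

    def __post_init__(self) -> None:
        if not (0 < self.target_ratio < 1):
            raise ValueError("target_ratio must be in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.itermax < 1:
            raise ValueError("itermax must be >= 1")


@dataclass
class FixationVector:
    """Per-frame fixation state plus threshold-search diagnostics."""

    fixation: np.ndarray  # (T,) bool; True only on valid frames
    valid: np.ndarray  # (T,) bool
    threshold: float
    converged: bool
    n_iter: int
    ratio: float

    @property
    def n_frames(self) -> int:
        return int(self.fixation.size)


def default_min_fix_frames(fps: float) -> int:
    """Minimum fixation persistence: 8 frames at 30 fps, scaled with fps."""
    return max(2, int(np.rint(fps * 8.0 / 30.0)))


def pupil_displacement(trace: NormalizedPupilTrace, eye: str) -> np.ndarray:
    """Frame-to-frame Euclidean displacement of one eye's normalized pupil.

    Length T, aligned to the later frame; NaN at frame 0 and wherever
    either endpoint of the difference is invalid.
    """
    pos = trace.eye(eye)
    valid = trace.valid(eye)
    d = np.full(pos.shape[0], np.nan)
    if pos.shape[0] < 2:
        return d
    diff = np.diff(pos, axis=0)
    dist = np.hypot(diff[:, 0], diff[:, 1])
    ok = valid[1:] & valid[:-1]
    d[1:] = np.where(ok, dist, np.nan)
    return d


def moving_average(values: Sequence[float], fps: float | None = None, q: int | None = None) -> np.ndarray:
    """Centered moving average with half-width q = ceil(fps / 30).

    Edges use the truncated window; NaN inputs are excluded from their
    windows (the window mean renormalizes over the finite entries).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if q is None:
        if fps is None:
            raise ValueError("either fps or q must be given")
        q = int(math.ceil(fps / 30.0))
    finite = np.isfinite(v)
    filled = np.where(finite, v, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(filled)])
    cc = np.concatenate([[0.0], np.cumsum(finite.astype(np.float64))])
    idx = np.arange(v.size)
    lo = np.maximum(0, idx - q)
    hi = np.minimum(v.size, idx + q + 1)
    sums = cs[hi] - cs[lo]
    counts = cc[hi] - cc[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def binocular_mean(left: Sequence[float], right: Sequence[float]) -> np.ndarray:
    """Mean of both eyes where both are defined, the defined one otherwise."""
    a = np.asarray(left, dtype=np.float64)
    b = np.asarray(right, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("left and right sequences must have equal length")
    fa, fb = np.isfinite(a), np.isfinite(b)
    out = np.where(fa & fb, 0.5 * (a + b), np.where(fa, a, b))
    return out


def compute_ear(frame: LandmarkFrame, eye_map: EyeLandmarkMap = DEFAULT_EYE_MAP,
                eye: str = "right") -> float:
    """Eye aspect ratio (|P2-P6| + |P3-P5|) / (2 |P1-P4|) for one frame."""
    ids = eye_map.eye(eye).ear
    try:
        p = np.array([frame.positions[i] for i in ids], dtype=np.float64)
    except KeyError as exc:
        raise KeyError(f"EAR landmark {exc} missing from frame") from None
    return _ear_from_points(p)


def _ear_from_points(p: np.ndarray) -> float:
    """EAR from the six points P1..P6 (P1/P4 horizontal corners)."""
    width = np.linalg.norm(p[0] - p[3])
    if width <= 0 or not np.isfinite(width):
        return float("nan")
    v1 = np.linalg.norm(p[1] - p[5])
    v2 = np.linalg.norm(p[2] - p[4])
    return float((v1 + v2) / (2.0 * width))


def ear_trace(stream: LandmarkStream, eye_map: EyeLandmarkMap = DEFAULT_EYE_MAP) -> np.ndarray:
    """(T, 2) EAR per frame; column 0 = left eye, column 1 = right eye."""
    out = np.full((stream.n_frames, 2), np.nan)
    for col, which in enumerate(("left", "right")):
        ids = eye_map.eye(which).ear
        p = stream.tracks(ids)  # (T, 6, 2)
        width = np.linalg.norm(p[:, 0] - p[:, 3], axis=1)
        v1 = np.linalg.norm(p[:, 1] - p[:, 5], axis=1)
        v2 = np.linalg.norm(p[:, 2] - p[:, 4], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ear = (v1 + v2) / (2.0 * width)
        ear[width <= 0] = np.nan
        out[:, col] = ear
    return out


def valid_mask(stream: LandmarkStream, eye_map: EyeLandmarkMap = DEFAULT_EYE_MAP,
               ear_threshold: float = DEFAULT_EAR_THRESHOLD) -> np.ndarray:
    """Frame validity: complete frame and both eyes' EAR >= threshold."""
    ear = ear_trace(stream, eye_map)
    complete = ~stream.incomplete_frames(eye_map)
    with np.errstate(invalid="ignore"):
        open_eyes = np.all(np.isfinite(ear) & (ear >= ear_threshold), axis=1)
    return complete & open_eyes


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal True runs as (start, end) inclusive."""
    out: List[Tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(np.int8), [0]])))
    for a, b in zip(idx[::2], idx[1::2]):
        out.append((int(a), int(b - 1)))
    return out


def fixation_runs(
    threshold: float,
    velocity: np.ndarray,
    valid: np.ndarray,
    min_fix_frames: int,
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Fixation mask and run list at a fixed threshold.

    Fixation frames are those inside maximal runs of
    (valid AND finite velocity AND velocity < threshold) at least
    ``min_fix_frames`` long. Invalid frames break runs.
    """
    vel = np.asarray(velocity, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        below = valid & np.isfinite(vel) & (vel < threshold)
    fix = np.zeros(vel.size, dtype=bool)
    runs: List[Tuple[int, int]] = []
    for a, b in _runs(below):
        if b - a + 1 >= min_fix_frames:
            fix[a : b + 1] = True
            runs.append((a, b))
    return fix, runs


def fixation_ratio_at(
    threshold: float,
    velocity: np.ndarray,
    valid: np.ndarray,
    min_fix_frames: int,
) -> Tuple[float, List[Tuple[int, int]]]:
    """Fraction of valid (finite-velocity) frames classified as fixation."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vel = np.asarray(velocity, dtype=np.float64)
    denom = int(np.sum(valid & np.isfinite(vel)))
    if denom == 0:
        raise ValueError("no valid frames with defined velocity")
    fix, runs = fixation_runs(threshold, vel, valid, min_fix_frames)
    return fix.sum() / denom, runs


def estimate_threshold(
    velocity: np.ndarray,
    valid: np.ndarray,
    fps: float,
    cfg: ThresholdSearchConfig | None = None,
) -> FixationVector:
    """Bisection search for the threshold meeting the target fixation ratio.

    Exploits monotonicity of the ratio in the threshold over
    [0, max smoothed velocity]. Never raises on an unattainable target: the
    best threshold is returned with ``converged=False``.
    """
    cfg = cfg or ThresholdSearchConfig()
    vel = np.asarray(velocity, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    if vel.shape != valid.shape:
        raise ValueError("velocity and valid mask must have equal length")
    minf = cfg.min_fix_frames or default_min_fix_frames(fps)
    usable = valid & np.isfinite(vel)
    if int(usable.sum()) < minf:
        raise ValueError("fewer valid frames than the minimum fixation length")

    vmax = float(np.max(vel[usable]))
    # nextafter keeps strict '<' able to include the largest velocity
    hi = np.nextafter(vmax, np.inf) if vmax > 0 else 1.0
    lo = 0.0
    best: Optional[Tuple[float, float, int]] = None  # (|dev|, threshold, it)
    converged = False
    n_iter = 0
    threshold = hi
    for it in range(1, cfg.itermax + 1):
        mid = 0.5 * (lo + hi)
        ratio, _ = fixation_ratio_at(mid, vel, valid, minf)
        dev = abs(ratio - cfg.target_ratio)
        if best is None or dev < best[0]:
            best = (dev, mid, it)
        n_iter = it
        if dev <= cfg.tolerance:
            threshold = mid
            converged = True
            break
        if ratio < cfg.target_ratio:
            lo = mid
        else:
            hi = mid
    if not converged:
        threshold = best[1]
    ratio, _ = fixation_ratio_at(threshold, vel, valid, minf)
    fix, _ = fixation_runs(threshold, vel, valid, minf)
    return FixationVector(
        fixation=fix,
        valid=valid.copy(),
        threshold=float(threshold),
        converged=converged,
        n_iter=n_iter,
        ratio=float(ratio),
    )


class FixationSegmenter(BaseEstimator):
    """sklearn-style estimator around the iterative threshold search.

    ``fit(velocity, valid=...)`` runs the bisection and exposes
    ``threshold_``, ``converged_``, ``ratio_``, ``n_iter_`` and
    ``min_fix_frames_``; ``predict`` returns the boolean fixation vector at
    the fitted threshold.
    """

    def __init__(
        self,
        fps: float = 30.0,
        target_ratio: float = 0.90,
        tolerance: float = 0.0025,
        itermax: int = 100,
        min_fix_frames: Optional[int] = None,
    ):
        self.fps = fps
        self.target_ratio = target_ratio
        self.tolerance = tolerance
        self.itermax = itermax
        self.min_fix_frames = min_fix_frames

    def _config(self) -> ThresholdSearchConfig:
        return ThresholdSearchConfig(
            target_ratio=self.target_ratio,
            tolerance=self.tolerance,
            itermax=self.itermax,
            min_fix_frames=self.min_fix_frames,
        )

    def fit(self, X, y=None, valid: Optional[np.ndarray] = None) -> "FixationSegmenter":
        vel = np.asarray(X, dtype=np.float64).reshape(-1)
        if valid is None:
            valid = np.isfinite(vel)
        result = estimate_threshold(vel, np.asarray(valid, dtype=bool), self.fps, self._config())
        self.threshold_ = result.threshold
        self.converged_ = result.converged
        self.ratio_ = result.ratio
        self.n_iter_ = result.n_iter
        self.min_fix_frames_ = self.min_fix_frames or default_min_fix_frames(self.fps)
        self.result_ = result
        return self

    def predict(self, X, valid: Optional[np.ndarray] = None) -> np.ndarray:
        vel = np.asarray(X, dtype=np.float64).reshape(-1)
        if valid is None:
            valid = np.isfinite(vel)
        fix, _ = fixation_runs(self.threshold_, vel, np.asarray(valid, dtype=bool),
                               self.min_fix_frames_)
        return fix
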