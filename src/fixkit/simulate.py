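"""Seeded synthetic gaze recordings with known ground truth.

The generator emulates a webcam face-mesh recording of a person scanning a
screen: an alternating fixation/saccade gaze process drives the pupil
landmarks of a template eye pair, on top of which slow similarity head
motion, per-landmark Gaussian jitter and blink events (collapsing the lid
landmarks, hence the EAR) are layered. Every recording carries its true
per-frame fixation vector and blink mask, so recovery can be scored at
frame level.

Default process parameters reflect typical free-viewing statistics:
fixation durations log-normal with median 0.25 s truncated to
[0.1, 0.6] s (mean ~0.27 s), saccades lasting 1-2 frames at 30 fps,
giving ~3.3 fixations/s and a fixation time fraction of ~0.87.

The template eye uses 16 reference points per eye (two horizontal corners
plus parabolic upper/lower lid arcs) sized so the open-eye EAR is 0.30 and
the blink minimum is ~0.05, bracketing the usual 0.2 blink threshold.
What the generator does **not** model: saccade kinematics (a 30 fps camera
cannot resolve them), microsaccades and drift inside fixations, pupil
diameter changes, detector dropouts, or non-rigid face deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .io import DEFAULT_EYE_MAP, EyeLandmarkMap, LandmarkStream

__all__ = ["GazeSimConfig", "Scanpath", "SimulatedRecording",
           "simulate_scanpath", "render_landmark_stream", "simulate_recording"]

OPEN_EAR = 0.30  # template eye aspect ratio with eyes open


@dataclass(frozen=True)
class GazeSimConfig:
    seed: int = 0
    fps: float = 30.0
    duration_s: float = 60.0
    # fixation duration distribution: log-normal, truncated by rejection
    fix_median_s: float = 0.25
    fix_sigma: float = 0.35
    fix_min_s: float = 0.1
    fix_max_s: float = 0.6
    # saccades last 1 or 2 frames
    p_two_frame_saccade: float = 0.2
    # fixation targets: pupil offsets uniform in +/- this box (pixels)
    target_halfrange_px: Tuple[float, float] = (15.0, 7.0)
    jitter_sd_px: float = 0.5
    # similarity head/camera motion
    head_rot_deg: float = 2.0
    head_scale_pct: float = 2.0
    head_trans_px: Tuple[float, float] = (10.0, 6.0)
    head_period_s: float = 8.0
    # blinks
    blink_rate_hz: float = 0.15
    blink_duration_s: float = 0.2
    blink_min_ear: float = 0.05

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if not (0 < self.fix_min_s <= self.fix_median_s <= self.fix_max_s):
            raise ValueError("need fix_min_s <= fix_median_s <= fix_max_s, all positive")
        if self.fix_sigma < 0 or self.blink_rate_hz < 0 or self.jitter_sd_px < 0:
            raise ValueError("rates and noise scales must be non-negative")
        if not (0 <= self.p_two_frame_saccade <= 1):
            raise ValueError("p_two_frame_saccade must be a probability")


@dataclass
class Scanpath:
    """Noise-free gaze process: pupil offset per frame plus ground truth."""

    positions: np.ndarray  # (T, 2) pupil offset from eye center, pixels
    fixation_true: np.ndarray  # (T,) bool
    fix_durations_s: List[float]
    fps: float

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_fixations(self) -> int:
        return len(self.fix_durations_s)

    @property
    def fixation_rate_hz(self) -> float:
        return self.n_fixations / (self.n_frames / self.fps)

    @property
    def mean_fix_duration_s(self) -> float:
        return float(np.mean(self.fix_durations_s)) if self.fix_durations_s else float("nan")


def _sample_fix_frames(rng: np.random.Generator, cfg: GazeSimConfig) -> int:
    """Truncated log-normal fixation duration, in frames (rejection sampling)."""
    if cfg.fix_sigma == 0:
        dur = cfg.fix_median_s
    else:
        mu = np.log(cfg.fix_median_s)
        for _ in range(1000):
            dur = rng.lognormal(mu, cfg.fix_sigma)
            if cfg.fix_min_s <= dur <= cfg.fix_max_s:
                break
        else:  # pragma: no cover - astronomically unlikely
            dur = cfg.fix_median_s
    return max(1, int(np.rint(dur * cfg.fps)))


def simulate_scanpath(cfg: GazeSimConfig) -> Scanpath:
    """Alternating fixation/saccade gaze sequence with ground truth.

    Fixation targets are drawn uniformly from the configured box; a
    saccade of s frames moves linearly and *arrives* on its last frame, so
    saccade frames are exactly the displacement-bearing frames.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    T = int(np.rint(cfg.duration_s * cfg.fps))
    half = np.asarray(cfg.target_halfrange_px, dtype=np.float64)
    pos = np.zeros((T, 2))
    truth = np.zeros(T, dtype=bool)
    durations: List[float] = []
    t = 0
    target = rng.uniform(-half, half)
    while t < T:
        n_fix = _sample_fix_frames(rng, cfg)
        end = min(t + n_fix, T)
        pos[t:end] = target
        truth[t:end] = True
        durations.append((end - t) / cfg.fps)
        t = end
        if t >= T:
            break
        new_target = rng.uniform(-half, half)
        n_sacc = 2 if rng.random() < cfg.p_two_frame_saccade else 1
        for j in range(1, n_sacc + 1):
            if t >= T:
                break
            pos[t] = target + (new_target - target) * (j / n_sacc)
            truth[t] = False
            t += 1
        target = new_target
    return Scanpath(positions=pos, fixation_true=truth,
                    fix_durations_s=durations, fps=cfg.fps)


# ---------------------------------------------------------------------------
# Landmark rendering
# ---------------------------------------------------------------------------

_EYE_HALF_WIDTH = 30.0
_LID_HEIGHT = 9.6  # parabola apex; gives open EAR = 0.30 at the EAR points
_IRIS_RADIUS = 5.0
_FACE_CENTER = np.array([320.0, 240.0])
_EYE_OFFSET_X = 40.0
_LID_XS = np.array([-22.5, -15.0, -7.5, 0.0, 7.5, 15.0, 22.5])


def _eye_template(eye, mirror: bool) -> Tuple[Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    """(lid landmark offsets, iris landmark offsets) for one eye.

    Reference ordering: corner, 7 upper-lid points, corner, 7 lower-lid
    points (matching the face-mesh contour order of the default map). Lid
    y follows a parabola; y is negative upward in image coordinates.
    """
    sign = -1.0 if mirror else 1.0
    a, h = _EYE_HALF_WIDTH, _LID_HEIGHT
    lid: Dict[int, np.ndarray] = {}
    ids = eye.reference
    lid[ids[0]] = np.array([sign * -a, 0.0])
    for k, x in enumerate(_LID_XS):
        lid[ids[1 + k]] = np.array([sign * x, -h * (1 - (x / a) ** 2)])
    lid[ids[8]] = np.array([sign * a, 0.0])
    for k, x in enumerate(_LID_XS[::-1]):
        lid[ids[9 + k]] = np.array([sign * x, h * (1 - (x / a) ** 2)])

    r = _IRIS_RADIUS
    p = eye.pupil  # (right, top, left, bottom, center) in map order
    iris = {
        p[0]: np.array([r, 0.0]),
        p[1]: np.array([0.0, -r]),
        p[2]: np.array([-r, 0.0]),
        p[3]: np.array([0.0, r]),
        p[4]: np.array([0.0, 0.0]),
    }
    return lid, iris


@dataclass
class SimulatedRecording:
    """A rendered landmark stream plus its ground truth."""

    stream: LandmarkStream
    fixation_true: np.ndarray  # (T,) bool
    blink_true: np.ndarray  # (T,) bool: noise-free EAR < 0.2
    ear_true: np.ndarray  # (T,) noise-free EAR
    scanpath: Scanpath
    config: GazeSimConfig = field(repr=False, default=None)


def _blink_openness(rng: np.random.Generator, cfg: GazeSimConfig, T: int) -> np.ndarray:
    """Per-frame lid openness in (0, 1]; triangular dips at Poisson times."""
    o = np.ones(T)
    if cfg.blink_rate_hz <= 0:
        return o
    o_min = cfg.blink_min_ear / OPEN_EAR
    n_blink = max(3, int(np.rint(cfg.blink_duration_s * cfg.fps)))
    if n_blink % 2 == 0:  # odd length so the dip attains o_min exactly
        n_blink += 1
    k = np.arange(n_blink)
    profile = 1.0 - (1.0 - o_min) * np.sin(np.pi * k / (n_blink - 1))
    t = rng.exponential(1.0 / cfg.blink_rate_hz) * cfg.fps
    while t < T:
        a = int(t)
        b = min(T, a + n_blink)
        o[a:b] = np.minimum(o[a:b], profile[: b - a])
        t += max(n_blink + 1, rng.exponential(1.0 / cfg.blink_rate_hz) * cfg.fps)
    return o


def render_landmark_stream(scanpath: Scanpath, cfg: GazeSimConfig,
                           eye_map: EyeLandmarkMap = DEFAULT_EYE_MAP) -> SimulatedRecording:
    """Render a scanpath into a full landmark stream.

    Layers, in order: template eye geometry driven by the gaze offsets
    (both eyes conjugate), blink lid collapse, global similarity head
    motion about the face center, and i.i.d. Gaussian landmark jitter.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    T = scanpath.n_frames
    fps = cfg.fps

    openness = _blink_openness(rng, cfg, T)
    ear_true = OPEN_EAR * openness
    blink_true = ear_true < 0.2

    landmark_ids = np.asarray(eye_map.required_ids)
    id_col = {int(i): c for c, i in enumerate(landmark_ids)}
    coords = np.empty((T, landmark_ids.size, 2))

    for which, mirror, ex in (("right", False, -_EYE_OFFSET_X), ("left", True, _EYE_OFFSET_X)):
        eye = eye_map.eye(which)
        lid, iris = _eye_template(eye, mirror)
        center = _FACE_CENTER + np.array([ex, 0.0])
        for lm, off in lid.items():
            xy = np.empty((T, 2))
            xy[:, 0] = center[0] + off[0]
            xy[:, 1] = center[1] + off[1] * openness  # blink collapses the lids
            coords[:, id_col[lm], :] = xy
        for lm, off in iris.items():
            coords[:, id_col[lm], :] = center + off + scanpath.positions
    # pupil-center ids share the gaze offset; overwrite with exact centers
    for which, ex in (("right", -_EYE_OFFSET_X), ("left", _EYE_OFFSET_X)):
        eye = eye_map.eye(which)
        center = _FACE_CENTER + np.array([ex, 0.0])
        coords[:, id_col[eye.pupil_center], :] = center + scanpath.positions

    # similarity head/camera motion about the face center
    if cfg.head_rot_deg or cfg.head_scale_pct or any(cfg.head_trans_px):
        phase = 2 * np.pi * np.arange(T) / (cfg.head_period_s * fps)
        ang = np.deg2rad(cfg.head_rot_deg) * np.sin(phase)
        scale = 1.0 + cfg.head_scale_pct / 100.0 * np.sin(phase + 1.3)
        tx = cfg.head_trans_px[0] * np.sin(phase + 2.1)
        ty = cfg.head_trans_px[1] * np.cos(phase + 0.7)
        rel = coords - _FACE_CENTER
        cos_a, sin_a = np.cos(ang), np.sin(ang)
        rx = cos_a[:, None] * rel[:, :, 0] - sin_a[:, None] * rel[:, :, 1]
        ry = sin_a[:, None] * rel[:, :, 0] + cos_a[:, None] * rel[:, :, 1]
        coords[:, :, 0] = _FACE_CENTER[0] + tx[:, None] + scale[:, None] * rx
        coords[:, :, 1] = _FACE_CENTER[1] + ty[:, None] + scale[:, None] * ry

    if cfg.jitter_sd_px > 0:
        coords = coords + rng.normal(0.0, cfg.jitter_sd_px, coords.shape)

    stream = LandmarkStream(
        fps=fps,
        frame_index=np.arange(T, dtype=np.int64),
        landmark_ids=landmark_ids,
        coords=coords,
    )
    return SimulatedRecording(
        stream=stream,
        fixation_true=scanpath.fixation_true.copy(),
        blink_true=blink_true,
        ear_true=ear_true,
        scanpath=scanpath,
        config=cfg,
    )


def simulate_recording(cfg: GazeSimConfig) -> SimulatedRecording:
    """Scanpath simulation + landmark rendering in one call."""
    return render_landmark_stream(simulate_scanpath(cfg), cfg)
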