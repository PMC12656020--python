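"""Per-frame affine gaze normalization.

Head and camera motion move the whole eye region rigidly (to good
approximation, a similarity transform). The normalizer undoes this per
frame and per eye using the stabilized reference landmarks:

1. translate by the reference centroid c,
2. de-rotate by the angle theta of the horizontal reference pair
   (atan2, positive clockwise in y-down image coordinates),
3. scale by s = min(1/x_range, 1/y_range) of the de-rotated references
   (one factor for both axes, preserving the eye's proportions),
4. re-center by +(1/2, 1/2).

The normalized pupil is  s * R(-theta) * (pupil - c) + (1/2, 1/2);  a pupil
sitting exactly at the reference centroid maps to (1/2, 1/2), and the
output is invariant under any similarity transform applied jointly to the
pupil and references. Parameters are recomputed every frame; frames whose
reference geometry is degenerate (zero range, coincident horizontal pair,
missing landmarks) are flagged invalid, never silently filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateFrameError
from .io import DEFAULT_EYE_MAP, EyeLandmarkMap, LandmarkStream

__all__ = [
    "AffineFrameParams",
    "NormalizedPupilTrace",
    "compute_affine_params",
    "normalize_pupil",
    "normalize_stream",
]

_EPS = 1e-12


@dataclass(frozen=True)
class AffineFrameParams:
    """Translation/rotation/scale for one frame of one eye."""

    centroid: np.ndarray
    theta: float
    scale: float

    @property
    def derotation(self) -> np.ndarray:
        """R(-theta); applied to centered coordinates."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, s], [-s, c]])


@dataclass
class NormalizedPupilTrace:
    """Per-frame, per-eye normalized pupil positions in the unit square."""

    frame_index: np.ndarray
    left: np.ndarray  # (T, 2), NaN where invalid
    right: np.ndarray
    valid_left: np.ndarray  # (T,) bool
    valid_right: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.size)

    def eye(self, which: str) -> np.ndarray:
        return self.left if which == "left" else self.right

    def valid(self, which: str) -> np.ndarray:
        return self.valid_left if which == "left" else self.valid_right


def compute_affine_params(refs: np.ndarray, horizontal_pair: np.ndarray) -> AffineFrameParams:
    """Normalization parameters from one frame's reference landmarks.

    ``refs``: (N, 2) stabilized reference positions (N = 16 by default);
    ``horizontal_pair``: (2, 2) the two horizontal reference points, angle
    taken from the first toward the second.
    """
    refs = np.asarray(refs, dtype=np.float64)
    hp = np.asarray(horizontal_pair, dtype=np.float64)
    if not (np.all(np.isfinite(refs)) and np.all(np.isfinite(hp))):
        raise DegenerateFrameError("non-finite reference landmarks")
    c = refs.mean(axis=0)
    delta = hp[1] - hp[0]
    if np.hypot(delta[0], delta[1]) <= _EPS:
        raise DegenerateFrameError("coincident horizontal reference pair")
    theta = float(np.arctan2(delta[1], delta[0]))
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    centered = refs - c
    x2 = cos_t * centered[:, 0] + sin_t * centered[:, 1]
    y2 = -sin_t * centered[:, 0] + cos_t * centered[:, 1]
    x_range = x2.max() - x2.min()
    y_range = y2.max() - y2.min()
    if x_range <= _EPS or y_range <= _EPS:
        raise DegenerateFrameError("zero reference range; frame geometry degenerate")
    s = min(1.0 / x_range, 1.0 / y_range)
    return AffineFrameParams(centroid=c, theta=theta, scale=s)


def normalize_pupil(pupil: np.ndarray, params: AffineFrameParams) -> np.ndarray:
    """Map a pupil position into the unit square with the frame's params."""
    p = np.asarray(pupil, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise DegenerateFrameError("non-finite pupil position")
    return params.scale * (params.derotation @ (p - params.centroid)) + 0.5


def _normalize_eye(
    refs: np.ndarray, hpair: np.ndarray, pupil: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-frame normalization for one eye.

    refs (T, N, 2), hpair (T, 2, 2), pupil (T, 2) -> (normalized (T, 2),
    valid (T,)). Degenerate or incomplete frames yield NaN + invalid.
    """
    T = refs.shape[0]
    with np.errstate(invalid="ignore"):
        c = refs.mean(axis=1)
        delta = hpair[:, 1, :] - hpair[:, 0, :]
        theta = np.arctan2(delta[:, 1], delta[:, 0])
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        centered = refs - c[:, None, :]
        x2 = cos_t[:, None] * centered[:, :, 0] + sin_t[:, None] * centered[:, :, 1]
        y2 = -sin_t[:, None] * centered[:, :, 0] + cos_t[:, None] * centered[:, :, 1]
        x_range = x2.max(axis=1) - x2.min(axis=1)
        y_range = y2.max(axis=1) - y2.min(axis=1)
        s = np.minimum(1.0 / np.maximum(x_range, _EPS), 1.0 / np.maximum(y_range, _EPS))
        pc = pupil - c
        out = np.empty((T, 2))
        out[:, 0] = s * (cos_t * pc[:, 0] + sin_t * pc[:, 1]) + 0.5
        out[:, 1] = s * (-sin_t * pc[:, 0] + cos_t * pc[:, 1]) + 0.5
    valid = (
        np.all(np.isfinite(refs), axis=(1, 2))
        & np.all(np.isfinite(hpair), axis=(1, 2))
        & np.all(np.isfinite(pupil), axis=1)
        & (np.hypot(delta[:, 0], delta[:, 1]) > _EPS)
        & (x_range > _EPS)
        & (y_range > _EPS)
    )
    out[~valid] = np.nan
    return out, valid


def normalize_stream(
    stream: LandmarkStream,
    eye_map: EyeLandmarkMap = DEFAULT_EYE_MAP,
    pupil_mode: Literal["center", "centroid"] = "center",
) -> NormalizedPupilTrace:
    """Normalize both eyes' pupil positions over a stabilized stream.

    ``pupil_mode`` selects the pupil position definition: ``center`` uses
    the dedicated pupil-center landmark (face-mesh 468/473), ``centroid``
    averages the five iris landmarks.
    """
    results = {}
    valids = {}
    for which in ("left", "right"):
        eye = eye_map.eye(which)
        refs = stream.tracks(eye.reference)
        hpair = stream.tracks(eye.horizontal)
        if pupil_mode == "center":
            pupil = stream.track(eye.pupil_center)
        elif pupil_mode == "centroid":
            pupil = stream.tracks(eye.pupil).mean(axis=1)
        else:
            raise ValueError("pupil_mode must be 'center' or 'centroid'")
        results[which], valids[which] = _normalize_eye(refs, hpair, pupil)
    return NormalizedPupilTrace(
        frame_index=stream.frame_index.copy(),
        left=results["left"],
        right=results["right"],
        valid_left=valids["left"],
        valid_right=valids["right"],
    )
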