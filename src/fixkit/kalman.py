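"""Constant-velocity Kalman denoising of landmark trajectories.

Each coordinate (x or y) of each landmark is filtered independently by a
2-state (position, velocity) Kalman filter with scalar position
observations:

    state transition  Ad = [[1, dt], [0, 1]]
    observation       C  = [1, 0]
    process noise     Q  = q * I2          (default q = 1)
    measurement noise R  = r               (default r = 100)
    initial covar     P0 = p0 * I2         (default p0 = 1)

The initial state uses the first three measurements: position is their mean,
velocity is (third - first) / (2 dt). Within a frame the filter corrects
with the new measurement first and then predicts the next frame, so the
reported estimate at frame t has consumed the measurement at t.

The defaults are deliberately conservative (r >> q): webcam landmark jitter
is treated as heavy measurement noise, which trades a few frames of lag for
a large variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import StreamValidationError
from .io import LandmarkStream

__all__ = ["KalmanConfig", "KalmanState", "KalmanSmoother",
           "init_state", "kalman_step", "smooth_track", "smooth_stream"]


def _as_cov(value, name: str) -> np.ndarray:
    """Expand a scalar to sigma*I2, or validate a 2x2 SPD-ish matrix."""
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.eye(2) * float(arr)
    if arr.shape != (2, 2):
        raise ValueError(f"{name} must be a scalar or 2x2 matrix")
    if not np.allclose(arr, arr.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.linalg.eigvalsh(arr) < -1e-12):
        raise ValueError(f"{name} must be positive semi-definite")
    return arr


@dataclass(frozen=True)
class KalmanConfig:
    """Filter matrices; scalars q/p0 expand to q*I2 / p0*I2."""

    dt: float = 1.0
    q: float | np.ndarray = 1.0
    r: float = 100.0
    p0: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("measurement noise r must be > 0")
        _as_cov(self.q, "q")
        _as_cov(self.p0, "p0")

    @property
    def Ad(self) -> np.ndarray:
        return np.array([[1.0, self.dt], [0.0, 1.0]])

    @property
    def C(self) -> np.ndarray:
        return np.array([1.0, 0.0])

    @property
    def Q(self) -> np.ndarray:
        return _as_cov(self.q, "q")

    @property
    def P0(self) -> np.ndarray:
        return _as_cov(self.p0, "p0")


@dataclass
class KalmanState:
    """Estimate x_hat = (position, velocity) with covariance P."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).reshape(2)
        self.P = np.asarray(self.P, dtype=np.float64).reshape(2, 2)


def init_state(first_three: Sequence[float], cfg: KalmanConfig | None = None) -> KalmanState:
    """Initial state from the first three measurements.

    Position is the mean of the three; velocity is the difference between
    the third and first measurement divided by the two elapsed time steps.
    """
    cfg = cfg or KalmanConfig()
    m = np.asarray(first_three, dtype=np.float64)
    if m.shape != (3,):
        raise ValueError("exactly 3 initial measurements required")
    if not np.all(np.isfinite(m)):
        raise ValueError("initial measurements must be finite")
    pos = m.mean()
    vel = (m[2] - m[0]) / (2.0 * cfg.dt)
    return KalmanState(x=np.array([pos, vel]), P=cfg.P0.copy())


def kalman_step(state: KalmanState, y: float, cfg: KalmanConfig | None = None) -> KalmanState:
    """One correct-then-predict update with scalar measurement ``y``.

    Correction: dy = y - C x;  K = P C' / (C P C' + r);  x += K dy;
    P = (I - K C) P.  Prediction: x = Ad x;  P = Ad P Ad' + Q.
    """
    cfg = cfg or KalmanConfig()
    if not np.isfinite(y):
        raise ValueError("measurement must be finite")
    Ad, C, Q, r = cfg.Ad, cfg.C, cfg.Q, cfg.r
    x, P = state.x.copy(), state.P.copy()
    dy = y - C @ x
    K = (P @ C) / (C @ P @ C + r)
    x = x + K * dy
    P = (np.eye(2) - np.outer(K, C)) @ P
    x = Ad @ x
    P = Ad @ P @ Ad.T + Q
    return KalmanState(x=x, P=P)


def smooth_track(values: Sequence[float], cfg: KalmanConfig | None = None) -> np.ndarray:
    """Filter one scalar trajectory; output has the same length.

    The first two outputs equal the initialization position (those frames
    are consumed by the three-point init); from t = 2 the output is the
    corrected position after consuming values[t]. NaN measurements skip the
    correction (prediction only) and yield NaN output for that frame.
    """
    cfg = cfg or KalmanConfig()
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    T = v.size
    if T < 3:
        raise StreamValidationError("at least 3 frames required for Kalman initialization")

    finite = np.isfinite(v)
    out = np.full(T, np.nan)
    first3 = np.flatnonzero(finite)[:3] if finite.any() else np.empty(0, int)
    if first3.size < 3:
        return out  # nothing to filter; all frames stay missing
    start = int(first3[-1])
    state = init_state(v[first3], cfg)
    out[: start + 1] = np.where(finite[: start + 1], state.x[0], np.nan)

    Ad, C, Q, r = cfg.Ad, cfg.C, cfg.Q, cfg.r
    x, P = state.x, state.P
    eye2 = np.eye(2)
    for t in range(start + 1, T):
        if finite[t]:
            dy = v[t] - x[0]
            K = (P @ C) / (P[0, 0] + r)
            x = x + K * dy
            P = (eye2 - np.outer(K, C)) @ P
            out[t] = x[0]
        # prediction advances the state whether or not a measurement arrived
        x = Ad @ x
        P = Ad @ P @ Ad.T + Q
    return out


class KalmanSmoother(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the filter column-wise.

    ``transform`` accepts (T,) or (T, n) arrays; each column is filtered
    independently. Stateless: ``fit`` only validates parameters.
    """

    def __init__(self, dt: float = 1.0, q: float = 1.0, r: float = 100.0, p0: float = 1.0):
        self.dt = dt
        self.q = q
        self.r = r
        self.p0 = p0

    def _config(self) -> KalmanConfig:
        return KalmanConfig(dt=self.dt, q=self.q, r=self.r, p0=self.p0)

    def fit(self, X, y=None) -> "KalmanSmoother":
        self._config()
        self.n_features_in_ = 1 if np.ndim(X) == 1 else np.shape(X)[1]
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            return smooth_track(X, cfg)
        return np.column_stack([smooth_track(X[:, j], cfg) for j in range(X.shape[1])])


def smooth_stream(stream: LandmarkStream, cfg: KalmanConfig | None = None) -> LandmarkStream:
    """Filter every landmark's x and y trajectories independently.

    Frames where a landmark is missing stay missing (flagged downstream as
    incomplete); no frame is dropped.
    """
    cfg = cfg or KalmanConfig()
    stream.validate(min_frames=3)
    out = np.empty_like(stream.coords)
    for k in range(stream.n_landmarks):
        for d in range(2):
            out[:, k, d] = smooth_track(stream.coords[:, k, d], cfg)
    return stream.with_coords(out)
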