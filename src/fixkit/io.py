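"""Landmark stream data model and IO.

Coordinates follow the image-pixel convention: origin top-left, x to the
right, y downward; frame indices are 0-based. A stream stores one (x, y)
position per (frame, landmark); missing detections are NaN and the frame is
considered *incomplete* with respect to an eye landmark map if any required
landmark is missing. Incomplete frames are carried through the pipeline with
a flag rather than dropped, so the time base stays intact.

The landmark ids follow the 478-point face-mesh convention with iris
refinement; :data:`RIGHT_EYE`, :data:`LEFT_EYE` and :data:`DEFAULT_EYE_MAP`
hold the per-eye index sets used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CapabilityError, FormatError, StreamValidationError

__all__ = [
    "LandmarkFrame",
    "LandmarkStream",
    "EyeIndexSet",
    "EyeLandmarkMap",
    "RIGHT_EYE",
    "LEFT_EYE",
    "DEFAULT_EYE_MAP",
    "read_landmark_stream",
    "write_landmark_stream",
    "detect_landmarks",
    "register_detector",
]


# ---------------------------------------------------------------------------
# Eye landmark index maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EyeIndexSet:
    """Face-mesh landmark ids describing one eye.

    ``ear`` is ordered P1..P6 with P1/P4 the horizontal eye corners, as in
    the standard eye-aspect-ratio formulation.
    """

    reference: Tuple[int, ...]
    pupil: Tuple[int, ...]
    pupil_center: int
    horizontal: Tuple[int, int]
    ear: Tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.reference) != 16:
            raise FormatError("expected 16 reference landmark ids")
        if len(self.pupil) != 5:
            raise FormatError("expected 5 pupil landmark ids")
        if len(self.ear) != 6:
            raise FormatError("expected 6 EAR landmark ids (P1..P6)")
        if self.pupil_center not in self.pupil:
            raise FormatError("pupil_center must be one of the pupil ids")
        if not (self.ear[0] in self.reference and self.ear[3] in self.reference):
            raise FormatError("EAR corner points P1/P4 must be reference landmarks")

    @property
    def all_ids(self) -> Tuple[int, ...]:
        ids = set(self.reference) | set(self.pupil) | set(self.horizontal) | set(self.ear)
        return tuple(sorted(ids))


@dataclass(frozen=True)
class EyeLandmarkMap:
    """Index sets for both eyes; the two eyes never share an id."""

    right: EyeIndexSet
    left: EyeIndexSet

    def __post_init__(self) -> None:
        if set(self.right.all_ids) & set(self.left.all_ids):
            raise FormatError("left- and right-eye landmark ids must be disjoint")

    def eye(self, which: str) -> EyeIndexSet:
        if which not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")
        return self.left if which == "left" else self.right

    @property
    def required_ids(self) -> Tuple[int, ...]:
        return tuple(sorted(set(self.right.all_ids) | set(self.left.all_ids)))


RIGHT_EYE = EyeIndexSet(
    reference=(33, 246, 161, 160, 159, 158, 157, 173, 133, 155, 154, 153, 145, 144, 163, 7),
    pupil=(469, 470, 471, 472, 468),
    pupil_center=468,
    horizontal=(471, 469),
    ear=(33, 160, 158, 133, 153, 144),
)

#: Standard face-mesh mirror of the right-eye ids.
LEFT_EYE = EyeIndexSet(
    reference=(263, 466, 388, 387, 386, 385, 384, 398, 362, 382, 381, 380, 374, 373, 390, 249),
    pupil=(474, 475, 476, 477, 473),
    pupil_center=473,
    horizontal=(476, 474),
    ear=(263, 387, 385, 362, 380, 373),
)

DEFAULT_EYE_MAP = EyeLandmarkMap(right=RIGHT_EYE, left=LEFT_EYE)


# ---------------------------------------------------------------------------
# Stream containers
# ---------------------------------------------------------------------------


@dataclass
class LandmarkFrame:
    """One frame's landmark positions, as a mapping landmark id -> (x, y)."""

    frame_index: int
    positions: Dict[int, np.ndarray]
    confidence: Optional[Dict[int, float]] = None

    def is_complete(self, required_ids: Iterable[int]) -> bool:
        return all(
            i in self.positions and np.all(np.isfinite(self.positions[i]))
            for i in required_ids
        )


@dataclass
class LandmarkStream:
    """Time-indexed landmark positions at a fixed frame rate.

    ``coords`` has shape (T, K, 2); column k holds the trajectory of
    ``landmark_ids[k]``. Missing positions are NaN.
    """

    fps: float
    frame_index: np.ndarray
    landmark_ids: np.ndarray
    coords: np.ndarray
    confidence: Optional[np.ndarray] = None
    _id_to_col: Dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.landmark_ids = np.asarray(self.landmark_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise StreamValidationError("coords must have shape (T, K, 2)")
        if self.coords.shape[0] != self.frame_index.shape[0]:
            raise StreamValidationError("frame_index length must match coords")
        if self.coords.shape[1] != self.landmark_ids.shape[0]:
            raise StreamValidationError("landmark_ids length must match coords")
        if self.fps <= 0:
            raise StreamValidationError("fps must be positive")
        if self.frame_index.size and np.any(np.diff(self.frame_index) <= 0):
            raise StreamValidationError("frame indices must be strictly increasing")
        if self.frame_index.size and self.frame_index[0] < 0:
            raise StreamValidationError("frame indices must be non-negative")
        self._id_to_col = {int(i): c for c, i in enumerate(self.landmark_ids)}

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_landmarks(self) -> int:
        return int(self.coords.shape[1])

    def has_landmark(self, landmark_id: int) -> bool:
        return int(landmark_id) in self._id_to_col

    def track(self, landmark_id: int) -> np.ndarray:
        """(T, 2) trajectory of one landmark."""
        try:
            return self.coords[:, self._id_to_col[int(landmark_id)], :]
        except KeyError:
            raise KeyError(f"landmark {landmark_id} not present in stream") from None

    def tracks(self, landmark_ids: Sequence[int]) -> np.ndarray:
        """(T, len(ids), 2) trajectories in the requested id order."""
        cols = [self._id_to_col[int(i)] for i in landmark_ids]
        return self.coords[:, cols, :]

    def frame(self, row: int) -> LandmarkFrame:
        pos = {
            int(i): self.coords[row, c].copy()
            for c, i in enumerate(self.landmark_ids)
        }
        conf = None
        if self.confidence is not None:
            conf = {int(i): float(self.confidence[row, c]) for c, i in enumerate(self.landmark_ids)}
        return LandmarkFrame(int(self.frame_index[row]), pos, conf)

    def incomplete_frames(self, eye_map: EyeLandmarkMap = DEFAULT_EYE_MAP) -> np.ndarray:
        """Boolean (T,) mask, True where any required landmark is missing."""
        required = [i for i in eye_map.required_ids if self.has_landmark(i)]
        if len(required) < len(eye_map.required_ids):
            return np.ones(self.n_frames, dtype=bool)
        sub = self.tracks(required)
        return ~np.all(np.isfinite(sub), axis=(1, 2))

    def with_coords(self, coords: np.ndarray) -> "LandmarkStream":
        """Copy of the stream with replaced coordinates (same ids/index)."""
        return replace(self, coords=np.asarray(coords, dtype=np.float64))

    def validate(self, min_frames: int = 3) -> "LandmarkStream":
        if self.n_frames < min_frames:
            raise StreamValidationError(
                f"stream has {self.n_frames} frames; at least {min_frames} required"
            )
        return self


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_COLUMNS = ("frame", "landmark", "x", "y")


def _stream_from_long(df: pd.DataFrame, fps: float, source: str) -> LandmarkStream:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")
    for col in ("x", "y") + (("conf",) if "conf" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        original_na = df[col].isna()
        bad = coerced.isna() & ~original_na
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"{source}: non-numeric value in column '{col}' at data row {row}")
        df[col] = coerced
    try:
        frames = pd.to_numeric(df["frame"]).astype(np.int64)
        lms = pd.to_numeric(df["landmark"]).astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{source}: non-integer frame/landmark column: {exc}") from exc

    dup = pd.DataFrame({"frame": frames, "landmark": lms}).duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(
            f"{source}: duplicate (frame={int(frames.iloc[row])}, "
            f"landmark={int(lms.iloc[row])}) at data row {row}"
        )

    frame_index = np.unique(frames.to_numpy())
    landmark_ids = np.unique(lms.to_numpy())
    fpos = {f: i for i, f in enumerate(frame_index)}
    lpos = {l: i for i, l in enumerate(landmark_ids)}
    coords = np.full((frame_index.size, landmark_ids.size, 2), np.nan)
    rows = frames.map(fpos).to_numpy()
    cols = lms.map(lpos).to_numpy()
    coords[rows, cols, 0] = df["x"].to_numpy(dtype=np.float64)
    coords[rows, cols, 1] = df["y"].to_numpy(dtype=np.float64)
    confidence = None
    if "conf" in df.columns:
        confidence = np.full((frame_index.size, landmark_ids.size), np.nan)
        confidence[rows, cols] = df["conf"].to_numpy(dtype=np.float64)
    return LandmarkStream(
        fps=fps,
        frame_index=frame_index,
        landmark_ids=landmark_ids,
        coords=coords,
        confidence=confidence,
    )


def read_landmark_stream(path: str | Path, fps: float) -> LandmarkStream:
    """Read a long-format landmark file (CSV or JSON) into a stream.

    CSV schema: header ``frame,landmark,x,y[,conf]``, one row per
    (frame, landmark). The JSON mirror is a list of objects with the same
    keys. Duplicate (frame, landmark) rows are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame.from_records(records)
        if df.empty:
            df = pd.DataFrame(columns=list(_COLUMNS))
    else:
        # round_trip parsing keeps write->read bit-exact on coordinates
        df = pd.read_csv(path, float_precision="round_trip")
    return _stream_from_long(df, fps=fps, source=str(path))


def stream_to_frame_table(stream: LandmarkStream) -> pd.DataFrame:
    """Long-format DataFrame (frame, landmark, x, y[, conf]); NaN rows dropped."""
    T, K, _ = stream.coords.shape
    frame = np.repeat(stream.frame_index, K)
    landmark = np.tile(stream.landmark_ids, T)
    x = stream.coords[:, :, 0].ravel()
    y = stream.coords[:, :, 1].ravel()
    data = {"frame": frame, "landmark": landmark, "x": x, "y": y}
    if stream.confidence is not None:
        data["conf"] = stream.confidence.ravel()
    df = pd.DataFrame(data)
    return df[np.isfinite(df["x"]) | np.isfinite(df["y"])].reset_index(drop=True)


def write_landmark_stream(stream: LandmarkStream, path: str | Path) -> None:
    """Write a stream as long-format CSV (or JSON if the path ends in .json).

    Values are written with full float precision so that
    :func:`read_landmark_stream` inverts this bit-exactly.
    """
    path = Path(path)
    df = stream_to_frame_table(stream)
    if path.suffix.lower() == ".json":
        records = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh)
    else:
        df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Detector adapters
# ---------------------------------------------------------------------------

DetectorAdapter = Callable[..., LandmarkStream]

_DETECTORS: Dict[str, DetectorAdapter] = {}


def register_detector(name: str) -> Callable[[DetectorAdapter], DetectorAdapter]:
    """Register a video-ingestion backend under ``name``.

    An adapter is a callable ``adapter(video_path, fps=None) -> LandmarkStream``
    producing one frame per decoded video frame.
    """

    def deco(fn: DetectorAdapter) -> DetectorAdapter:
        _DETECTORS[name] = fn
        return fn

    return deco


@register_detector("null")
def _null_detector(video: str | Path, fps: Optional[float] = None) -> LandmarkStream:
    """Produces an empty stream; placeholder when no face-mesh backend exists.

    Container fps cannot be probed without a video decoder, so ``fps`` is an
    argument (default 30).
    """
    return LandmarkStream(
        fps=fps or 30.0,
        frame_index=np.empty(0, dtype=np.int64),
        landmark_ids=np.asarray(DEFAULT_EYE_MAP.required_ids),
        coords=np.empty((0, len(DEFAULT_EYE_MAP.required_ids), 2)),
    )


def detect_landmarks(video: str | Path, backend: str = "null", fps: Optional[float] = None) -> LandmarkStream:
    """Run a registered face-mesh backend on a video file.

    The tested core consumes landmark CSV/JSON; this is the pluggable entry
    point for optional video ingestion.
    """
    if backend not in _DETECTORS:
        raise CapabilityError(
            f"detector backend '{backend}' is not registered; "
            "extract landmarks externally and provide a landmark CSV instead"
        )
    return _DETECTORS[backend](video, fps=fps)
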