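"""Per-bin fixation features.

The boolean fixation vector is cut into maximal fixation segments and
aggregated into contiguous, non-overlapping bins (default 3 s, starting at
frame 0; a trailing partial bin is emitted and flagged). Each segment is
assigned to the bin containing its onset frame, so fixation counts
partition across bins. Features per bin:

* FC — fixation count (segments with onset in the bin),
* FR — fixation frames in the bin / valid frames in the bin,
* mean / median / SD / variance / skewness / kurtosis of the onset
  segments' durations (seconds).

Moments are population moments (ddof = 0); skewness is Fisher-Pearson g1
and kurtosis is excess g2, reported as missing for n < 3 / n < 4 or when
the durations are all equal. Bins with no fixation carry FC = 0, FR = 0
and missing duration statistics; bins with no valid frames have FR missing
as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segment import FixationVector

__all__ = ["FixationSegment", "extract_segments", "compute_feature_table"]

FEATURE_COLUMNS = [
    "bin_start_s", "bin_end_s", "fc", "fr",
    "mean_afd_s", "median_afd_s", "sd_afd_s", "var_afd_s",
    "skew_afd", "kurt_afd", "partial",
]


@dataclass(frozen=True)
class FixationSegment:
    """One maximal fixation run; frames inclusive, duration in seconds."""

    start: int
    end: int
    duration_s: float

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def extract_segments(fix: FixationVector | np.ndarray, fps: float) -> List[FixationSegment]:
    """Maximal TRUE runs of the fixation vector as segments."""
    mask = fix.fixation if isinstance(fix, FixationVector) else np.asarray(fix, dtype=bool)
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(np.int8), [0]])))
    return [
        FixationSegment(start=int(a), end=int(b - 1), duration_s=(b - a) / fps)
        for a, b in zip(idx[::2], idx[1::2])
    ]


def _duration_stats(durations: np.ndarray) -> dict:
    n = durations.size
    out = {k: np.nan for k in ("mean_afd_s", "median_afd_s", "sd_afd_s",
                               "var_afd_s", "skew_afd", "kurt_afd")}
    if n == 0:
        return out
    out["mean_afd_s"] = float(durations.mean())
    out["median_afd_s"] = float(np.median(durations))
    var = float(durations.var(ddof=0))
    out["var_afd_s"] = var
    out["sd_afd_s"] = math.sqrt(var)
    if var > 0 and n >= 3:
        out["skew_afd"] = float(stats.skew(durations, bias=True))
    if var > 0 and n >= 4:
        out["kurt_afd"] = float(stats.kurtosis(durations, fisher=True, bias=True))
    return out


def compute_feature_table(
    segments: Sequence[FixationSegment],
    fix: FixationVector,
    fps: float,
    bin_seconds: float = 3.0,
) -> pd.DataFrame:
    """Aggregate segments and the fixation vector into per-bin features."""
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be > 0")
    T = fix.n_frames
    frames_per_bin = bin_seconds * fps
    n_bins = max(1, int(math.ceil(T / frames_per_bin)))
    rows = []
    for b in range(n_bins):
        a = int(round(b * frames_per_bin))
        z = min(T, int(round((b + 1) * frames_per_bin)))
        onsets = np.array([s.duration_s for s in segments if a <= s.start < z])
        n_valid = int(fix.valid[a:z].sum())
        n_fix = int(fix.fixation[a:z].sum())
        row = {
            "bin_start_s": a / fps,
            "bin_end_s": z / fps,
            "fc": int(onsets.size),
            "fr": (n_fix / n_valid) if n_valid > 0 else np.nan,
            "partial": z - a < int(round(frames_per_bin)),
        }
        row.update(_duration_stats(onsets))
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
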