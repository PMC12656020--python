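"""OPTICS density clustering and sliding-window fixation-center stabilization.

The clustering is implemented from scratch (no library call) because the
method's behaviour depends on conventions that must be pinned down exactly:

* ``MinPts`` is derived from the frame rate as ``round(fps * 0.3)`` and
  counts *neighbors*; a point's neighborhood includes the point itself, so a
  core point at 30 fps needs 10 points (9 neighbors + itself) within reach.
* Core distance of a point is the Euclidean distance to its MinPts-th
  nearest *other* point, undefined beyond ``eps_max``.
* Reachability of p from o is ``max(core_distance(o), dist(o, p))``; points
  are processed by a global seed priority of (smallest current reachability,
  then smallest original index), each exactly once.
* Clusters are cut out of the ordered reachability profile with the
  canonical xi-steepness extraction, then gated: a cluster is recognized
  only if it holds at least ``ceil(min_cluster_fraction * window_size)``
  points (25% of a 90-frame window = 23 frames at 30 fps, 3 s).

Stabilization runs this per frame on a window centered at t and replaces
the frame-t position by its cluster's center when the point belongs to a
gated cluster, leaving it bit-identical otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import StreamValidationError
from .io import LandmarkStream

__all__ = [
    "OpticsConfig",
    "ReachabilityProfile",
    "ClusterExtraction",
    "OpticsStabilizer",
    "derive_minpts",
    "compute_optics",
    "extract_clusters",
    "stabilize_trajectory",
    "stabilize_stream",
]


@dataclass(frozen=True)
class OpticsConfig:
    window_seconds: float = 3.0
    minpts_factor: float = 0.3
    min_cluster_fraction: float = 0.25
    eps_max: float = math.inf
    xi: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_cluster_fraction <= 1):
            raise ValueError("min_cluster_fraction must be in (0, 1]")
        if self.minpts_factor <= 0:
            raise ValueError("minpts_factor must be > 0")
        if not (0 < self.xi < 1):
            raise ValueError("xi must be in (0, 1)")
        if not (0.0 < self.window_seconds):
            raise ValueError("window_seconds must be > 0")


def derive_minpts(fps: float, cfg: OpticsConfig | None = None) -> int:
    """Neighbor count MinPts = round(fps * minpts_factor).

    The returned value counts neighbors excluding the point itself, so the
    required neighborhood size is MinPts + 1 points.
    """
    cfg = cfg or OpticsConfig()
    if fps <= 0:
        raise ValueError("fps must be > 0")
    minpts = int(np.rint(fps * cfg.minpts_factor))
    if minpts < 2:
        raise ValueError(
            f"MinPts={minpts} at fps={fps} is degenerate; need at least 2 neighbors"
        )
    return minpts


@dataclass
class ReachabilityProfile:
    """OPTICS output for one point set.

    ``ordering`` is a permutation of 0..n-1; ``reachability[j]`` is the
    reachability of point ``ordering[j]`` at the moment it was processed
    (NaN = undefined, always so for the first point of an expansion);
    ``core_distance`` is indexed by original point index (NaN = undefined).
    """

    ordering: np.ndarray
    reachability: np.ndarray
    core_distance: np.ndarray
    minpts: int
    eps_max: float


def compute_optics(
    points: Sequence[Sequence[float]] | np.ndarray,
    minpts: int,
    eps_max: float = math.inf,
) -> ReachabilityProfile:
    """Core distances, reachability distances and the processing order."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    n = pts.shape[0]
    if n < minpts + 1:
        raise ValueError(f"need at least minpts+1={minpts + 1} points, got {n}")

    D = cdist(pts, pts)
    # minpts-th nearest other point == (minpts+1)-th order statistic incl. self
    core = np.partition(D, minpts, axis=1)[:, minpts]
    core = np.where(core <= eps_max, core, np.nan)

    processed = np.zeros(n, dtype=bool)
    reach = np.full(n, np.inf)
    ordering = np.empty(n, dtype=np.int64)
    reach_out = np.full(n, np.nan)
    for step in range(n):
        candidates = np.flatnonzero(~processed)
        i = candidates[np.argmin(reach[candidates])]
        ordering[step] = i
        if np.isfinite(reach[i]):
            reach_out[step] = reach[i]
        processed[i] = True
        if np.isfinite(core[i]):
            upd = np.maximum(core[i], D[i])
            mask = ~processed & (D[i] <= eps_max)
            reach[mask] = np.minimum(reach[mask], upd[mask])
    return ReachabilityProfile(
        ordering=ordering,
        reachability=reach_out,
        core_distance=core,
        minpts=minpts,
        eps_max=eps_max,
    )


# ---------------------------------------------------------------------------
# xi-steepness cluster extraction
# ---------------------------------------------------------------------------


def _extend_steep_region(steep: np.ndarray, against: np.ndarray, index: int, max_flat: int) -> int:
    """Last index (exclusive) of the steep region starting at ``index``.

    Up to ``max_flat`` consecutive non-steep points are tolerated as long as
    they do not move against the region's direction.
    """
    n = steep.size
    end = index
    index += 1
    flat = 0
    while index < n:
        if steep[index]:
            flat = 0
            end = index
        elif not against[index]:
            flat += 1
            if flat > max_flat:
                break
        else:
            break
        index += 1
    return end + 1


def _xi_clusters(reachability: np.ndarray, minpts: int, xi: float,
                 min_cluster_size: int) -> List[tuple]:
    """Candidate clusters as (start, end) positions in the ordering.

    Canonical steep-area extraction over the reachability profile: steep
    down areas are matched with subsequent steep up areas, subject to the
    maximum-in-between (mib) significance conditions.
    """
    r = np.where(np.isfinite(reachability), reachability, np.inf)
    rp = np.append(r, np.inf)  # sentinel terminates a trailing cluster
    xc = 1.0 - xi
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = rp[:-1] / rp[1:]
    steep_up = ratio <= xc
    steep_down = ratio >= 1.0 / xc
    up = ratio < 1.0
    down = ratio > 1.0

    clusters: List[tuple] = []
    sdas: List[dict] = []
    index = 0
    mib = 0.0
    n = steep_up.size
    while index < n:
        mib = max(mib, rp[index])
        if steep_down[index]:
            sdas = [d for d in sdas if rp[d["start"]] * xc >= mib]
            for d in sdas:
                d["mib"] = max(d["mib"], mib)
            start = index
            index = _extend_steep_region(steep_down, up, index, minpts)
            sdas.append({"start": start, "end": index - 1, "mib": 0.0})
            mib = rp[index] if index < rp.size else np.inf
        elif steep_up[index]:
            sdas = [d for d in sdas if rp[d["start"]] * xc >= mib]
            for d in sdas:
                d["mib"] = max(d["mib"], mib)
            u_start = index
            index = _extend_steep_region(steep_up, down, index, minpts)
            u_end = index - 1
            mib = rp[index] if index < rp.size else np.inf
            for d in sdas:
                c_start, c_end = d["start"], u_end
                r_end = rp[c_end + 1]
                # significance of the separation on both flanks
                if r_end * xc < d["mib"]:
                    continue
                d_max = rp[d["start"]]
                if d_max * xc >= r_end:
                    while c_start < d["end"] and rp[c_start + 1] > r_end:
                        c_start += 1
                elif r_end * xc >= d_max:
                    while c_end > u_start and rp[c_end - 1] > d_max:
                        c_end -= 1
                if c_start > d["end"] or c_end < u_start:
                    continue
                if c_end - c_start + 1 < min_cluster_size:
                    continue
                clusters.append((c_start, c_end))
        else:
            index += 1
    return clusters


@dataclass
class ClusterExtraction:
    """Gated clusters and per-point assignment for one window.

    ``clusters`` are the minimal (leaf) xi clusters, hence pairwise
    disjoint; ``gated`` indexes those meeting the size gate; ``centers``
    holds the mean member position per gated cluster; ``assignment`` maps
    each window point to its gated cluster index or -1.
    """

    clusters: List[np.ndarray]
    gated: List[int]
    centers: List[np.ndarray]
    assignment: np.ndarray
    gate_size: int
    candidates: List[tuple] = field(default_factory=list)


def extract_clusters(
    profile: ReachabilityProfile,
    points: np.ndarray,
    cfg: OpticsConfig | None = None,
    window_size: Optional[int] = None,
) -> ClusterExtraction:
    """xi-steepness extraction followed by the minimum-size gate.

    Nested xi candidates are resolved by keeping the minimal (leaf)
    clusters, which are disjoint by construction of the hierarchy. The gate
    requires ``ceil(min_cluster_fraction * window_size)`` members.
    """
    cfg = cfg or OpticsConfig()
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    window_size = n if window_size is None else int(window_size)
    gate = int(math.ceil(cfg.min_cluster_fraction * window_size))

    # extract at the gate size directly: sub-gate valleys are never usable,
    # and skipping them keeps genuine clusters from being shadowed by
    # spurious nested leaves
    cand = sorted(set(_xi_clusters(profile.reachability, profile.minpts, cfg.xi,
                                   min_cluster_size=max(2, profile.minpts + 1, gate))))
    # keep leaves: candidates that contain no other candidate
    leaves = [
        (s, e)
        for (s, e) in cand
        if not any((s2 >= s and e2 <= e and (s2, e2) != (s, e)) for (s2, e2) in cand)
    ]
    leaves.sort()
    clusters = [profile.ordering[s : e + 1].copy() for (s, e) in leaves]
    gated = [i for i, m in enumerate(clusters) if m.size >= gate]
    centers = [pts[clusters[i]].mean(axis=0) for i in gated]
    assignment = np.full(n, -1, dtype=np.int64)
    for gi, ci in enumerate(gated):
        assignment[clusters[ci]] = gi
    return ClusterExtraction(
        clusters=clusters,
        gated=gated,
        centers=centers,
        assignment=assignment,
        gate_size=gate,
        candidates=cand,
    )


# ---------------------------------------------------------------------------
# Sliding-window stabilization
# ---------------------------------------------------------------------------


def window_length(fps: float, cfg: OpticsConfig | None = None) -> int:
    """Window length round(window_seconds * fps), forced odd for symmetry."""
    cfg = cfg or OpticsConfig()
    n = int(np.rint(cfg.window_seconds * fps))
    if n % 2 == 0:
        n += 1
    return n


def stabilize_trajectory(
    track: np.ndarray,
    fps: float,
    cfg: OpticsConfig | None = None,
) -> np.ndarray:
    """Replace in-cluster positions by their cluster center, per frame.

    For each frame t the window {t-n/2 .. t+n/2} of finite positions is
    clustered; if the frame-t point lies in a gated cluster the output is
    that cluster's center, otherwise the input position is passed through
    bit-identically. At the recording edges the window is truncated
    *symmetrically* (both half-windows shrink together), keeping the frame
    centered so one-sided spill-over cannot bias cluster centers; windows
    with fewer than MinPts+1 usable points pass positions through
    unchanged.
    """
    cfg = cfg or OpticsConfig()
    pts = np.asarray(track, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("track must have shape (T, 2)")
    T = pts.shape[0]
    minpts = derive_minpts(fps, cfg)
    n = window_length(fps, cfg)
    half = n // 2
    out = pts.copy()
    finite = np.all(np.isfinite(pts), axis=1)
    for t in range(T):
        if not finite[t]:
            continue
        half_t = min(half, t, T - 1 - t)
        a, b = t - half_t, t + half_t + 1
        idx = np.flatnonzero(finite[a:b]) + a
        if idx.size < minpts + 1:
            continue
        win = pts[idx]
        profile = compute_optics(win, minpts, cfg.eps_max)
        extraction = extract_clusters(profile, win, cfg, window_size=b - a)
        pos_in_win = int(np.searchsorted(idx, t))
        gi = extraction.assignment[pos_in_win]
        if gi >= 0:
            out[t] = extraction.centers[gi]
    return out


class OpticsStabilizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer for one 2-D trajectory.

    ``transform`` accepts (T, 2) arrays (a single landmark trajectory) and
    returns the stabilized trajectory. Stateless apart from parameter
    validation in ``fit``.
    """

    def __init__(
        self,
        fps: float = 30.0,
        window_seconds: float = 3.0,
        minpts_factor: float = 0.3,
        min_cluster_fraction: float = 0.25,
        eps_max: float = math.inf,
        xi: float = 0.05,
    ):
        self.fps = fps
        self.window_seconds = window_seconds
        self.minpts_factor = minpts_factor
        self.min_cluster_fraction = min_cluster_fraction
        self.eps_max = eps_max
        self.xi = xi

    def _config(self) -> OpticsConfig:
        return OpticsConfig(
            window_seconds=self.window_seconds,
            minpts_factor=self.minpts_factor,
            min_cluster_fraction=self.min_cluster_fraction,
            eps_max=self.eps_max,
            xi=self.xi,
        )

    def fit(self, X, y=None) -> "OpticsStabilizer":
        derive_minpts(self.fps, self._config())
        return self

    def transform(self, X) -> np.ndarray:
        return stabilize_trajectory(np.asarray(X, dtype=np.float64), self.fps, self._config())


def stabilize_stream(stream: LandmarkStream, cfg: OpticsConfig | None = None) -> LandmarkStream:
    """Stabilize every landmark trajectory of a (Kalman-smoothed) stream."""
    cfg = cfg or OpticsConfig()
    stream.validate(min_frames=3)
    out = np.empty_like(stream.coords)
    for k in range(stream.n_landmarks):
        out[:, k, :] = stabilize_trajectory(stream.coords[:, k, :], stream.fps, cfg)
    return stream.with_coords(out)
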