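import math

import numpy as np
import pytest
from sklearn.cluster import OPTICS as SkOPTICS

from fixkit.optics import (
    OpticsConfig,
    OpticsStabilizer,
    compute_optics,
    derive_minpts,
    extract_clusters,
    stabilize_trajectory,
    window_length,
)


def brute_optics(points, minpts, eps_max=math.inf):
    """Pure-python O(n^2) transcription of the OPTICS definition.

    Core distance: distance to the minpts-th nearest other point.
    Reachability of p from o: max(core(o), d(o, p)). Processing by the
    global priority (smallest reachability, then smallest index).
    """
    n = len(points)
    dist = [
        [math.hypot(points[i][0] - points[j][0], points[i][1] - points[j][1]) for j in range(n)]
        for i in range(n)
    ]
    core = []
    for i in range(n):
        others = sorted(dist[i][j] for j in range(n) if j != i)
        cd = others[minpts - 1]
        core.append(cd if cd <= eps_max else None)
    reach = [None] * n
    processed = [False] * n
    order, order_reach = [], []
    for _ in range(n):
        best = None
        for i in range(n):
            if processed[i]:
                continue
            key = (reach[i] if reach[i] is not None else math.inf, i)
            if best is None or key < best:
                best = key
                pick = i
        order.append(pick)
        order_reach.append(reach[pick])
        processed[pick] = True
        if core[pick] is not None:
            for j in range(n):
                if not processed[j] and dist[pick][j] <= eps_max:
                    cand = max(core[pick], dist[pick][j])
                    if reach[j] is None or cand < reach[j]:
                        reach[j] = cand
    return order, order_reach, core


class TestDeriveMinpts:
    def test_30_fps_needs_ten_point_neighborhood(self):
        # 9 neighbors plus the point itself = the documented 10 points
        assert derive_minpts(30.0) == 9

    def test_scales_with_fps(self):
        assert derive_minpts(60.0) == 18

    def test_degenerate_low_fps_rejected(self):
        with pytest.raises(ValueError):
            derive_minpts(3.0)


class TestComputeOptics:
    def test_identical_points_all_zero_distances(self):
        prof = compute_optics(np.zeros((20, 2)), minpts=3)
        assert np.all(prof.core_distance == 0.0)
        assert np.isnan(prof.reachability[0])
        np.testing.assert_array_equal(prof.reachability[1:], 0.0)
        assert sorted(prof.ordering.tolist()) == list(range(20))

    def test_collinear_hand_enumeration(self):
        pts = np.array([[i, 0.0] for i in range(5)])
        prof = compute_optics(pts, minpts=2)
        np.testing.assert_array_equal(prof.core_distance, [2, 1, 1, 1, 2])
        np.testing.assert_array_equal(prof.ordering, [0, 1, 2, 3, 4])
        assert np.isnan(prof.reachability[0])
        np.testing.assert_array_equal(prof.reachability[1:], [2, 1, 1, 1])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compute_optics(np.zeros((5, 2)), minpts=5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (60, 2))
        prof = compute_optics(pts, minpts=5)
        order, order_reach, core = brute_optics(pts.tolist(), 5)
        assert prof.ordering.tolist() == order
        np.testing.assert_allclose(prof.core_distance, core, atol=1e-12)
        expect = [math.nan if r is None else r for r in order_reach]
        np.testing.assert_allclose(prof.reachability, expect, atol=1e-12)

    def test_reachability_values_match_sklearn(self, rng):
        # independent library cross-check (ordering tie-breaks differ,
        # the reachability profile's multiset of values must not)
        pts = np.vstack([rng.normal((0, 0), 0.3, (30, 2)), rng.normal((8, 0), 0.3, (30, 2))])
        prof = compute_optics(pts, minpts=9)
        sk = SkOPTICS(min_samples=10).fit(pts)
        np.testing.assert_allclose(prof.core_distance, sk.core_distances_, atol=1e-12)
        mine = np.sort(prof.reachability[1:])
        theirs = np.sort(sk.reachability_[np.isfinite(sk.reachability_)])
        np.testing.assert_allclose(mine, theirs, atol=1e-12)


class TestExtractClusters:
    def test_gate_size_23_frames_at_30fps_3s_window(self):
        cfg = OpticsConfig(window_seconds=3.0, min_cluster_fraction=0.25)
        assert math.ceil(cfg.min_cluster_fraction * 90) == 23
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 0.4, (90, 2))
        ext = extract_clusters(compute_optics(pts, 9), pts, cfg, window_size=90)
        assert ext.gate_size == 23

    def test_single_blob_gated(self, rng):
        pts = rng.normal((5, 5), 0.3, (90, 2))
        ext = extract_clusters(compute_optics(pts, 9), pts, OpticsConfig())
        assert len(ext.gated) == 1
        assert ext.clusters[ext.gated[0]].size >= ext.gate_size
        np.testing.assert_allclose(ext.centers[0], pts.mean(axis=0), atol=0.5)

    def test_three_blobs_recovered(self, rng):
        pts = np.vstack([
            rng.normal((0, 0), 0.3, (30, 2)),
            rng.normal((10, 0), 0.3, (30, 2)),
            rng.normal((5, 8), 0.3, (30, 2)),
        ])
        labels = np.repeat([0, 1, 2], 30)
        ext = extract_clusters(compute_optics(pts, 9), pts, OpticsConfig())
        assert len(ext.gated) == 3
        found = {frozenset(labels[ext.clusters[c]].tolist()) for c in ext.gated}
        assert found == {frozenset({0}), frozenset({1}), frozenset({2})}

    def test_small_blob_below_gate_not_recognized(self, rng):
        pts = np.vstack([rng.normal((50, 50), 0.5, (10, 2)), rng.uniform(0, 100, (80, 2))])
        ext = extract_clusters(compute_optics(pts, 9), pts, OpticsConfig())
        blob = set(range(10))
        for c in ext.gated:
            assert set(ext.clusters[c].tolist()) != blob

    def test_gate_monotone_in_fraction(self, rng):
        pts = np.vstack([rng.normal((0, 0), 0.3, (40, 2)), rng.normal((9, 0), 0.3, (25, 2)),
                         rng.uniform(-5, 15, (25, 2))])
        prof = compute_optics(pts, 9)
        counts = []
        for frac in (0.1, 0.25, 0.4, 0.6, 0.9):
            ext = extract_clusters(prof, pts, OpticsConfig(min_cluster_fraction=frac))
            counts.append(len(ext.gated))
        assert counts == sorted(counts, reverse=True)

    def test_gated_clusters_disjoint(self, rng):
        pts = np.vstack([rng.normal((0, 0), 0.4, (45, 2)), rng.normal((6, 0), 0.4, (45, 2))])
        ext = extract_clusters(compute_optics(pts, 9), pts, OpticsConfig())
        seen = set()
        for c in ext.gated:
            members = set(ext.clusters[c].tolist())
            assert not members & seen
            seen |= members


class TestStabilize:
    def test_window_length_is_odd(self):
        assert window_length(30.0) == 91
        assert window_length(20.0) == 61

    def test_stationary_track_dispersion_reduced(self, rng):
        track = np.tile([5.0, 5.0], (120, 1)) + rng.normal(0, 0.4, (120, 2))
        out = stabilize_trajectory(track, 30.0)
        assert out.shape == track.shape
        assert out.std(axis=0).mean() < track.std(axis=0).mean()

    def test_two_fixation_track(self, rng):
        track = np.vstack([np.tile([0.0, 0.0], (45, 1)), np.tile([20.0, 0.0], (45, 1))])
        track += rng.normal(0, 0.3, track.shape)
        out = stabilize_trajectory(track, 30.0)
        for sl, target in ((slice(0, 45), (0, 0)), (slice(45, 90), (20, 0))):
            din = np.linalg.norm(track[sl] - track[sl].mean(0), axis=1).mean()
            dout = np.linalg.norm(out[sl] - out[sl].mean(0), axis=1).mean()
            assert dout < din
            assert np.linalg.norm(out[sl].mean(0) - target) < 0.5

    def test_unclustered_frames_bit_identical(self, rng):
        # a track jumping every few frames never forms gate-sized clusters
        targets = rng.uniform(-20, 20, (30, 2))
        track = np.repeat(targets, 4, axis=0) + rng.normal(0, 0.05, (120, 2))
        out = stabilize_trajectory(track, 30.0)
        ext_changed = np.any(out != track, axis=1)
        # whatever was not replaced is the exact input, not a rounded copy
        np.testing.assert_array_equal(out[~ext_changed], track[~ext_changed])

    def test_short_track_passthrough(self, rng):
        track = rng.normal(0, 1, (8, 2))  # < MinPts+1 usable points
        out = stabilize_trajectory(track, 30.0)
        np.testing.assert_array_equal(out, track)

    def test_nan_frames_passed_through(self, rng):
        track = np.tile([1.0, 1.0], (60, 1)) + rng.normal(0, 0.2, (60, 2))
        track[10] = np.nan
        out = stabilize_trajectory(track, 30.0)
        assert np.all(np.isnan(out[10]))

    def test_estimator_api_matches_function(self, rng):
        track = np.tile([2.0, 3.0], (60, 1)) + rng.normal(0, 0.3, (60, 2))
        est = OpticsStabilizer(fps=30.0)
        np.testing.assert_array_equal(est.fit(track).transform(track),
                                      stabilize_trajectory(track, 30.0))
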