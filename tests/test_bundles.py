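"""Hausdorff distances, bundle clustering, hull areas and foci."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from myoscale.bundles import (
    FiberTrace,
    bundle_area,
    cluster_bundles,
    count_foci,
    FociSet,
    hausdorff_distance,
    hausdorff_points,
    pairwise_hausdorff,
    resample_trace,
)
from myoscale.synthetic import gen_trace_set


def brute_hausdorff(a, b):
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def random_trace(rng, tid, n=12, scale=30.0):
    pts = np.cumsum(rng.uniform(-1, 1, (n, 2)), axis=0) * scale / n
    pts += rng.uniform(0, scale, 2)
    return FiberTrace(tid, pts)


class TestHausdorff:
    def test_identical_traces_have_zero_distance(self):
        t = FiberTrace("a", [(0, 0), (5, 5), (10, 3)])
        assert hausdorff_distance(t, t) == 0.0

    def test_parallel_offset_segments(self):
        a = FiberTrace("a", [(0.0, 0.0), (10.0, 0.0)])
        b = FiberTrace("b", [(0.0, 2.0), (10.0, 2.0)])
        assert hausdorff_distance(a, b) == pytest.approx(2.0)

    def test_definition_on_tiny_point_sets(self):
        # directed distances differ; the symmetric distance is the larger
        assert hausdorff_points([(0, 0)], [(0, 0), (10, 0)]) == pytest.approx(10.0)

    def test_matches_brute_force_oracle(self, rng):
        for k in range(25):
            a = random_trace(rng, "a", n=rng.integers(5, 50))
            b = random_trace(rng, "b", n=rng.integers(5, 50))
            d = hausdorff_distance(a, b, resample_um=None)
            assert d == pytest.approx(brute_hausdorff(a.points, b.points), abs=1e-12)

    def test_symmetry_and_triangle_inequality(self, rng):
        traces = [random_trace(rng, f"t{i}") for i in range(12)]
        for _ in range(50):
            i, j, k = rng.choice(12, 3, replace=False)
            dij = hausdorff_distance(traces[i], traces[j])
            dji = hausdorff_distance(traces[j], traces[i])
            dik = hausdorff_distance(traces[i], traces[k])
            dkj = hausdorff_distance(traces[k], traces[j])
            assert dij == pytest.approx(dji, abs=1e-12)
            assert dij <= dik + dkj + 1e-9

    def test_resampling_removes_density_dependence(self):
        dense = FiberTrace("d", np.column_stack([np.linspace(0, 10, 100),
                                                 np.zeros(100)]))
        sparse = FiberTrace("s", [(0.0, 1.0), (10.0, 1.0)])
        assert hausdorff_distance(dense, sparse, resample_um=0.5) == pytest.approx(
            1.0, abs=1e-9)


class TestTraceValidation:
    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            FiberTrace("a", [(0, 0)])

    def test_rejects_repeated_consecutive_points(self):
        with pytest.raises(ValueError):
            FiberTrace("a", [(0, 0), (0, 0), (1, 1)])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            FiberTrace("a", [(0, 0), (np.nan, 1)])

    def test_resample_keeps_endpoints(self):
        t = FiberTrace("a", [(0.0, 0.0), (3.0, 4.0)])
        pts = resample_trace(t, 1.0)
        assert np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (3, 4))
        steps = np.hypot(*np.diff(pts, axis=0).T)
        assert np.all(steps <= 1.0 + 1e-9)


class TestClustering:
    def three_chain(self):
        return [
            FiberTrace("A", [(0.0, 0.0), (10.0, 0.0)]),
            FiberTrace("B", [(0.0, 3.0), (10.0, 3.0)]),
            FiberTrace("C", [(0.0, 6.0), (10.0, 6.0)]),
        ]

    def test_tiny_threshold_gives_singletons(self):
        bs = cluster_bundles(self.three_chain(), 0.5)
        assert bs.n_bundles == 3

    def test_huge_threshold_gives_one_bundle(self):
        bs = cluster_bundles(self.three_chain(), 100.0)
        assert bs.n_bundles == 1

    def test_transitive_chain_forms_one_bundle(self):
        # d(A,B)=3 < 4, d(B,C)=3 < 4, d(A,C)=6 > 4: transitive closure
        bs = cluster_bundles(self.three_chain(), 4.0)
        assert bs.n_bundles == 1
        assert len(set(bs.assignments.values())) == 1

    def test_labels_deterministic_by_smallest_trace_id(self):
        bs = cluster_bundles(self.three_chain(), 0.5)
        assert bs.assignments["A"] == 0
        assert bs.assignments["B"] == 1
        assert bs.assignments["C"] == 2

    def test_cluster_count_non_increasing_in_threshold(self, rng):
        traces = [random_trace(rng, f"t{i:02d}") for i in range(15)]
        counts = [cluster_bundles(traces, t).n_bundles
                  for t in (1.0, 5.0, 10.0, 20.0, 50.0, 200.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_partition_recovered(self):
        traces, labels, foci, truth = gen_trace_set(
            n_bundles=4, traces_per_bundle=5, trace_length_um=200.0,
            n_vertices=30, seed=11)
        lo = truth.parameters["max_within_hausdorff_um"]
        hi = truth.parameters["min_between_hausdorff_um"]
        bs = cluster_bundles(traces, (lo + hi) / 2)
        got = {}
        for tid, lab in bs.assignments.items():
            got.setdefault(lab, set()).add(tid)
        want = {}
        for tid, lab in labels.items():
            want.setdefault(lab, set()).add(tid)
        assert set(map(frozenset, got.values())) == set(map(frozenset, want.values()))

    def test_point_count_conserved(self, rng):
        traces = [random_trace(rng, f"t{i:02d}") for i in range(8)]
        bs = cluster_bundles(traces, 10.0)
        per_bundle = 0
        for lab in set(bs.assignments.values()):
            per_bundle += sum(len(t.points) for t in traces
                              if bs.assignments[t.trace_id] == lab)
        assert per_bundle == sum(len(t.points) for t in traces)

    def test_validation(self):
        with pytest.raises(ValueError):
            cluster_bundles([], 1.0)
        with pytest.raises(ValueError):
            cluster_bundles(self.three_chain(), -1.0)


def gift_wrap_shoelace(points):
    """Independent convex-hull area oracle: gift wrapping + shoelace."""
    pts = np.unique(np.asarray(points, float), axis=0)
    if len(pts) < 3:
        return 0.0
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u, v = pts[cand] - pts[cur], pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0
                             and np.linalg.norm(pts[j] - pts[cur])
                             > np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    h = pts[hull]
    x, y = h[:, 0], h[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestBundleArea:
    def test_unit_square(self):
        traces = [FiberTrace(f"t{i}", [p, (p[0] + 1e-3, p[1])])
                  for i, p in enumerate([(0.0, 0.0), (1.0, 0.0),
                                         (1.0, 1.0), (0.0, 1.0)])]
        assert bundle_area(traces) == pytest.approx(1.0, abs=1e-2)

    def test_collinear_points_have_zero_area(self):
        t = FiberTrace("a", [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
        assert bundle_area([t]) == 0.0

    def test_matches_gift_wrapping_oracle(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 100, (50, 2))
            t = FiberTrace("a", pts)
            expect = gift_wrap_shoelace(pts)
            assert bundle_area([t]) == pytest.approx(expect, rel=1e-9)


from hypothesis import given, settings
from hypothesis import strategies as st

finite_pts = st.lists(
    st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    min_size=1, max_size=20,
).map(np.array)


class TestHausdorffProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=finite_pts, b=finite_pts)
    def test_metric_axioms_on_point_sets(self, a, b):
        d = hausdorff_points(a, b)
        assert d >= 0
        assert d == pytest.approx(hausdorff_points(b, a), abs=1e-12)
        assert hausdorff_points(a, a) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=finite_pts, b=finite_pts, c=finite_pts)
    def test_triangle_inequality(self, a, b, c):
        assert hausdorff_points(a, b) <= (
            hausdorff_points(a, c) + hausdorff_points(c, b) + 1e-9)


class TestFoci:
    def test_empty_and_small_counts(self):
        assert count_foci(FociSet(np.empty((0, 2)))) == 0
        assert count_foci(FociSet([(0, 0), (1, 1), (2, 2)])) == 3

    def test_duplicate_points_counted_with_warning(self):
        with pytest.warns(UserWarning):
            n = count_foci(FociSet([(0.0, 0.0), (0.0, 0.0)]))
        assert n == 2
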