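"""Hausdorff-distance clustering of traced fibers into bundles.

Manually traced fiber polylines (one per myotube/myofiber) are grouped into
bundles: every pair of traces whose symmetric Hausdorff distance falls below
a threshold is linked, and bundles are the connected components of that
graph. Each bundle is summarised by its convex-hull area over the union of
member points. Attachment foci — points where bundle ends converge — are
consumed as manually placed point lists and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import directed_hausdorff
from shapely.geometry import MultiPoint

__all__ = [
    "FiberTrace",
    "BundleSet",
    "FociSet",
    "resample_trace",
    "hausdorff_points",
    "hausdorff_distance",
    "pairwise_hausdorff",
    "cluster_bundles",
    "bundle_area",
    "count_foci",
]


@dataclass
class FiberTrace:
    """An ordered polyline tracing one fiber, in micrometres.

    ``metadata`` carries free-form labels (day, well, category, ...).
    """

    trace_id: str
    points: np.ndarray  # (n, 2) x, y in µm
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError(f"trace {self.trace_id!r}: need >= 2 (x, y) points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"trace {self.trace_id!r}: coordinates must be finite")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError(f"trace {self.trace_id!r}: consecutive points must differ")

    @property
    def length_um(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


@dataclass
class BundleSet:
    """Cluster assignment of traces into bundles plus per-bundle hull areas."""

    assignments: Dict[str, int]  # trace_id -> bundle label
    areas_um2: Dict[int, float]  # bundle label -> convex-hull area
    threshold_um: float

    @property
    def n_bundles(self) -> int:
        return len(set(self.assignments.values()))

    def members(self, label: int) -> List[str]:
        return [t for t, b in self.assignments.items() if b == label]


@dataclass
class FociSet:
    """Manually traced attachment foci as (x, y) points in µm."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def count(self) -> int:
        return len(self.points)


def resample_trace(trace: FiberTrace, spacing_um: float = 1.0) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing.

    Keeps both endpoints; the number of samples is ``ceil(L/spacing) + 1``
    so the effective spacing is at most ``spacing_um``. Removes the
    dependence of Hausdorff distances on hand-tracing point density.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    seg = np.hypot(*np.diff(trace.points, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(np.ceil(total / spacing_um)), 1) + 1
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arc, trace.points[:, 0])
    y = np.interp(s, arc, trace.points[:, 1])
    return np.column_stack([x, y])


def hausdorff_points(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two bare point sets."""
    a = np.asarray(a, float).reshape(-1, 2)
    b = np.asarray(b, float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def hausdorff_distance(
    a: FiberTrace, b: FiberTrace, resample_um: float | None = 1.0
) -> float:
    """Symmetric Hausdorff distance between two traces, in µm.

    ``max(h(A->B), h(B->A))`` where ``h(A->B)`` is the maximum over points
    of A of the distance to the nearest point of B. Traces are resampled to
    uniform arc-length spacing first (pass ``resample_um=None`` for the raw
    hand-traced vertices).
    """
    pa = resample_trace(a, resample_um) if resample_um else a.points
    pb = resample_trace(b, resample_um) if resample_um else b.points
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def pairwise_hausdorff(
    traces: Sequence[FiberTrace], resample_um: float | None = 1.0
) -> np.ndarray:
    """Symmetric pairwise Hausdorff distance matrix over a trace set."""
    pts = [
        resample_trace(t, resample_um) if resample_um else t.points for t in traces
    ]
    n = len(pts)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = max(
                directed_hausdorff(pts[i], pts[j])[0],
                directed_hausdorff(pts[j], pts[i])[0],
            )
    return d


def cluster_bundles(
    traces: Sequence[FiberTrace],
    threshold_um: float,
    resample_um: float | None = 1.0,
) -> BundleSet:
    """Group traces into bundles by thresholded Hausdorff distance.

    Bundles are the connected components of the graph whose edges join
    trace pairs with distance strictly below ``threshold_um`` (single
    linkage at a hard threshold — the transitive closure of the pairwise
    rule). Labels are deterministic: bundles are numbered 0, 1, ... in
    order of their smallest member ``trace_id``.
    """
    if not traces:
        raise ValueError("need at least one trace")
    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")
    ids = [t.trace_id for t in traces]
    if len(set(ids)) != len(ids):
        raise ValueError("trace_ids must be unique")

    d = pairwise_hausdorff(traces, resample_um)
    ii, jj = np.nonzero(d < threshold_um)
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=d.shape)
    _, comp = connected_components(adj, directed=False)

    # relabel components by their smallest member trace_id
    first = {}
    for idx in sorted(range(len(ids)), key=lambda k: ids[k]):
        first.setdefault(comp[idx], len(first))
    assignments = {ids[k]: first[comp[k]] for k in range(len(ids))}

    areas: Dict[int, float] = {}
    for label in set(assignments.values()):
        members = [traces[k] for k in range(len(ids)) if assignments[ids[k]] == label]
        areas[label] = bundle_area(members)

    return BundleSet(assignments=assignments, areas_um2=areas, threshold_um=threshold_um)


def bundle_area(traces: Sequence[FiberTrace]) -> float:
    """Convex-hull area (µm²) of the union of all member trace points.

    Collinear or otherwise degenerate point sets have area 0.
    """
    if not traces:
        raise ValueError("bundle needs at least one trace")
    pts = np.vstack([t.points for t in traces])
    return float(MultiPoint(pts).convex_hull.area)


def count_foci(foci: FociSet) -> int:
    """Number of attachment foci (duplicated points are counted twice)."""
    if len(foci.points) != len(np.unique(foci.points, axis=0)):
        warnings.warn("duplicated foci points retained and counted", stacklevel=2)
    return foci.count
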