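"""Per-fiber scalar morphometrics.

Length of traced fiber polylines, manually measured widths, nuclei counts
from local maxima of DAPI intensity sampled along the traces, and wide-line
mean-intensity quantification of marker channels (e.g. a 50-pixel-wide line
ROI averaged over its whole length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from myoscale.bundles import FiberTrace

__all__ = [
    "LineProfile",
    "NucleiResult",
    "trace_length",
    "sample_line_profile",
    "count_nuclei",
    "measure_width",
    "max_project",
]


@dataclass
class LineProfile:
    """Intensity sampled along a polyline, optionally width-averaged."""

    positions: np.ndarray  # µm along the trace
    intensities: np.ndarray
    mean_intensity: float = float("nan")

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must match")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be increasing")


@dataclass
class NucleiResult:
    """Nuclei detected as intensity maxima along a fiber trace."""

    peak_positions_um: np.ndarray
    threshold_used: float

    @property
    def count(self) -> int:
        return len(self.peak_positions_um)


def trace_length(trace: FiberTrace) -> float:
    """Polyline length in µm: sum of consecutive segment lengths."""
    return trace.length_um


def sample_line_profile(
    image: np.ndarray,
    trace: FiberTrace,
    pixel_size: float,
    width_px: int = 1,
) -> LineProfile:
    """Sample image intensity along a trace with a given line width.

    The trace (µm coordinates) is resampled at one-pixel arc-length steps;
    at each step the intensity is bilinearly interpolated at ``width_px``
    samples spread perpendicular to the trace (1 px apart, centred on it)
    and averaged. ``mean_intensity`` over the whole profile is the
    wide-line measure used for relative protein levels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")

    pts_px = trace.points / pixel_size
    seg = np.hypot(*np.diff(pts_px, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.floor(arc[-1])), 1) + 1
    s = np.arange(n, dtype=float)
    path = np.column_stack([np.interp(s, arc, pts_px[:, k]) for k in range(2)])

    t = np.gradient(path, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    normal = np.column_stack([-t[:, 1], t[:, 0]])
    offs = np.arange(width_px, dtype=float) - (width_px - 1) / 2

    cx = path[:, 0, None] + offs[None, :] * normal[:, 0, None]
    cy = path[:, 1, None] + offs[None, :] * normal[:, 1, None]
    if (cx.min() < 0 or cx.max() > img.shape[1] - 1
            or cy.min() < 0 or cy.max() > img.shape[0] - 1):
        raise ValueError("widened trace exits the image")

    vals = map_coordinates(img, [cy, cx], order=1).mean(axis=1)
    return LineProfile(
        positions=s * pixel_size,
        intensities=vals,
        mean_intensity=float(vals.mean()),
    )


def count_nuclei(
    profile: LineProfile,
    threshold: float,
    min_separation_um: float = 5.0,
) -> NucleiResult:
    """Count nuclei as local intensity maxima above a threshold.

    Maxima must be strictly above ``threshold``; plateaus count once at
    their center; maxima closer than ``min_separation_um`` are merged
    keeping the higher.
    """
    if len(profile.intensities) < 3:
        raise ValueError("profile needs >= 3 samples")
    dx = float(np.mean(np.diff(profile.positions)))
    distance = max(min_separation_um / dx, 1.0)
    peaks, _ = find_peaks(
        profile.intensities,
        height=np.nextafter(threshold, np.inf),
        distance=distance,
    )
    return NucleiResult(
        peak_positions_um=profile.positions[peaks],
        threshold_used=float(threshold),
    )


def measure_width(
    image: Optional[np.ndarray],
    segment: FiberTrace,
    pixel_size: float = 1.0,
) -> float:
    """Fiber width from a manual perpendicular segment, in µm.

    The segment itself is the measurement (its Euclidean end-to-end
    length, scaled by ``pixel_size`` — pass 1.0 when the points are
    already in µm); the image argument is accepted for provenance only.
    """
    if len(segment.points) != 2:
        raise ValueError("width segment must have exactly 2 points")
    d = float(np.hypot(*(segment.points[1] - segment.points[0])))
    if d == 0:
        raise ValueError("zero-length width segment")
    return d * pixel_size


def max_project(volume: np.ndarray, z_start: int, z_stop: int) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) volume over [z_start, z_stop)."""
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    if not (0 <= z_start < z_stop <= vol.shape[0]):
        raise ValueError("invalid z range")
    return vol[z_start:z_stop].max(axis=0)
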