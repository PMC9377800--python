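"""Nematic orientation statistics of fiber-texture images.

A fluorescence image of a fiber culture is reduced to a coarse grid of local
orientation angles via the structure tensor, and the grid is summarised by
the statistics used to quantify tissue-scale alignment:

* the spatial correlation ``C(d) = 2<cos^2(theta(r) - theta(r+d))> - 1``
  averaged over all grid-point pairs at distance ``d``;
* the nematic length ``eta_L``, the x-intercept of the initial linear decay
  of ``C(d)``;
* the local nematic order ``S = sqrt(<cos 2theta>^2 + <sin 2theta>^2)`` over
  square windows of grid cells (default 4x4);
* the fraction of disorder, the fraction of windows with ``S`` below a
  threshold (default 0.5).

Angle convention: 0 rad along the image x-axis, counter-clockwise positive
with the y-axis pointing up (i.e. against the raster row direction), nematic
range ``[-pi/2, pi/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist

__all__ = [
    "OrientationField",
    "CorrelationCurve",
    "OrderMap",
    "NematicSummary",
    "compute_orientation_field",
    "spatial_correlation",
    "nematic_length",
    "local_nematic_order",
    "disorder_fraction",
    "nematic_summary",
    "wrap_nematic",
    "nematic_difference",
]


def wrap_nematic(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to the nematic range [-pi/2, pi/2)."""
    return np.mod(np.asarray(theta) + np.pi / 2, np.pi) - np.pi / 2


def nematic_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest angular difference between two nematic angles, in [0, pi/2]."""
    d = np.abs(wrap_nematic(np.asarray(a) - np.asarray(b)))
    return np.minimum(d, np.pi - d)


@dataclass
class OrientationField:
    """Grid of nematic orientation angles extracted from an image.

    Attributes
    ----------
    angles
        2D array of orientation angles in radians, each in [-pi/2, pi/2).
    grid_spacing
        Pixels between grid centers.
    origin_offset
        Pixel coordinate (same along both axes) of the first grid center.
    pixel_size
        Micrometres per pixel.
    valid_mask
        Boolean grid marking cells with sufficient image energy.
    """

    angles: np.ndarray
    grid_spacing: float
    origin_offset: float
    pixel_size: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.angles.ndim != 2:
            raise ValueError("angles must be a 2D grid")
        if self.valid_mask.shape != self.angles.shape:
            raise ValueError("valid_mask must have the same shape as angles")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        a = self.angles[np.isfinite(self.angles)]
        if a.size and (a.min() < -np.pi / 2 - 1e-12 or a.max() >= np.pi / 2 + 1e-12):
            raise ValueError("angles must lie in [-pi/2, pi/2)")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class CorrelationCurve:
    """Orientation spatial correlation C(d) by exact grid distance class."""

    distances_grid: np.ndarray  # grid units, strictly increasing
    distances_um: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.distances_grid = np.asarray(self.distances_grid, dtype=float)
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if np.any(np.diff(self.distances_grid) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(self.pair_counts < 1):
            raise ValueError("each distance class needs at least one pair")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("C(d) must lie in [-1, 1]")


@dataclass
class OrderMap:
    """Local nematic order S per non-overlapping window of grid cells."""

    S_values: np.ndarray
    window_mask: np.ndarray  # True where the window had >= 1 valid cell
    window_cells: int
    centers_um: np.ndarray  # (n_rows, n_cols, 2) window center positions, µm

    def __post_init__(self) -> None:
        s = self.S_values[self.window_mask]
        if s.size and (s.min() < -1e-9 or s.max() > 1 + 1e-9):
            raise ValueError("S must lie in [0, 1]")


@dataclass
class NematicSummary:
    """Scalar alignment summary of one orientation field."""

    nematic_length_um: Optional[float]
    disorder_fraction: float
    threshold_used: float = 0.5
    parameters: dict = field(default_factory=dict)


def compute_orientation_field(
    image: np.ndarray,
    sigma: float = 10.0,
    grid_size: int = 100,
    pixel_size: float = 1.0,
    inner_scale: float = 1.0,
    energy_floor: float = 1e-3,
) -> OrientationField:
    """Extract one dominant local orientation per grid cell of an image.

    Image gradients are taken with Gaussian derivatives at ``inner_scale``
    pixels; the structure tensor components are averaged with a Gaussian
    window of ``sigma`` pixels; the orientation of each grid-block center is
    the eigenvector of the locally averaged tensor associated with its
    smaller eigenvalue (i.e. along the ridges of the texture). Cells whose
    tensor trace falls below ``energy_floor`` times the image-wide mean
    trace are masked invalid.

    Parameters
    ----------
    image
        Single-channel 2D intensity array.
    sigma
        Structure-tensor local averaging window, pixels.
    grid_size
        Side of the square blocks over which one orientation is reported;
        the orientation is evaluated at each block center.
    pixel_size
        Micrometres per pixel.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty single-channel 2D array")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (1 <= grid_size <= min(img.shape)):
        raise ValueError("grid_size must be >= 1 and <= the smaller image dimension")

    gx = gaussian_filter(img, inner_scale, order=(0, 1))
    # negate the row derivative so the y-axis points up (CCW-positive angles)
    gy = -gaussian_filter(img, inner_scale, order=(1, 0))
    jxx = gaussian_filter(gx * gx, sigma)
    jxy = gaussian_filter(gx * gy, sigma)
    jyy = gaussian_filter(gy * gy, sigma)

    off = grid_size // 2
    r_idx = np.arange(img.shape[0] // grid_size) * grid_size + off
    c_idx = np.arange(img.shape[1] // grid_size) * grid_size + off

    cxx = jxx[np.ix_(r_idx, c_idx)]
    cxy = jxy[np.ix_(r_idx, c_idx)]
    cyy = jyy[np.ix_(r_idx, c_idx)]

    # 0.5*atan2(2Jxy, Jxx-Jyy) is the dominant-gradient orientation; the
    # ridge orientation is perpendicular to it
    theta = wrap_nematic(0.5 * np.arctan2(2 * cxy, cxx - cyy) + np.pi / 2)

    trace = cxx + cyy
    mean_trace = float((jxx + jyy).mean())
    valid = trace >= energy_floor * mean_trace if mean_trace > 0 else np.zeros_like(trace, bool)

    return OrientationField(
        angles=theta,
        grid_spacing=float(grid_size),
        origin_offset=float(off),
        pixel_size=float(pixel_size),
        valid_mask=valid,
    )


def spatial_correlation(
    field: OrientationField,
    max_distance_grid: Optional[float] = None,
    decimals: int = 6,
) -> CorrelationCurve:
    """Orientation correlation C(d) over all valid grid-cell pairs.

    For each realised inter-cell distance class (exact Euclidean distances
    on the grid, rounded to ``decimals`` decimals in grid units, up to
    ``max_distance_grid``, default half the grid diagonal),
    ``C(d) = 2<cos^2(dtheta)> - 1 = <cos 2 dtheta>`` over all valid pairs at
    that distance. ``C(0) = 1`` by construction and is included.
    """
    rr, cc = np.nonzero(field.valid_mask)
    if rr.size < 2:
        raise ValueError("need at least 2 valid cells")
    if max_distance_grid is None:
        max_distance_grid = 0.5 * float(np.hypot(*field.angles.shape))

    pos = np.column_stack([cc, rr]).astype(float)  # grid units
    th = field.angles[rr, cc]
    u = np.column_stack([np.cos(2 * th), np.sin(2 * th)])

    d = pdist(pos)
    # |u_i - u_j|^2 = 2 - 2 cos(2 dtheta) for unit vectors
    cos2d = 1.0 - 0.5 * pdist(u, "sqeuclidean")

    keep = d <= max_distance_grid + 1e-12
    d = np.round(d[keep], decimals)
    cos2d = cos2d[keep]

    classes, inverse = np.unique(d, return_inverse=True)
    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=cos2d)
    values = sums / counts

    classes = np.concatenate([[0.0], classes])
    values = np.clip(np.concatenate([[1.0], values]), -1.0, 1.0)
    counts = np.concatenate([[rr.size], counts])

    um = classes * field.grid_spacing * field.pixel_size
    return CorrelationCurve(classes, um, values, counts)


def nematic_length(curve: CorrelationCurve, floor: float = 0.5) -> Optional[float]:
    """Nematic length eta_L: x-intercept of the initial linear decay of C(d).

    A straight line is fitted by ordinary least squares to the leading
    points of the curve with ``C >= floor`` (at least 2 points), and eta_L
    is that line's x-intercept, in micrometres. Returns ``None`` (undefined)
    when the curve never decays below the floor or the fitted slope is
    non-negative.
    """
    if curve.values.size < 3:
        raise ValueError("need at least 3 distance classes")
    if curve.values.min() >= floor:
        return None  # never decays below the floor (e.g. uniform field)

    below = np.nonzero(curve.values < floor)[0]
    n_lead = max(int(below[0]), 2)
    x = curve.distances_um[:n_lead]
    y = curve.values[:n_lead]
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        return None
    return float(-intercept / slope)


def local_nematic_order(field: OrientationField, window_cells: int = 4) -> OrderMap:
    """Local nematic order S per non-overlapping window of grid cells.

    ``S = sqrt(mean(cos 2theta)^2 + mean(sin 2theta)^2)`` over the valid
    cells of each ``window_cells x window_cells`` window; windows with no
    valid cell are masked. Trailing cells that do not fill a window are
    dropped.
    """
    nr, nc = field.angles.shape
    w = int(window_cells)
    if w < 1 or w > min(nr, nc):
        raise ValueError("window_cells must be >= 1 and fit in the field")

    nwr, nwc = nr // w, nc // w
    th = field.angles[: nwr * w, : nwc * w].reshape(nwr, w, nwc, w)
    vm = field.valid_mask[: nwr * w, : nwc * w].reshape(nwr, w, nwc, w)

    n = vm.sum(axis=(1, 3)).astype(float)
    c = np.where(vm, np.cos(2 * th), 0.0).sum(axis=(1, 3))
    s = np.where(vm, np.sin(2 * th), 0.0).sum(axis=(1, 3))
    mask = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.hypot(c / n, s / n)
    S[~mask] = np.nan

    step = w * field.grid_spacing * field.pixel_size
    orig = (field.origin_offset + (w - 1) * field.grid_spacing / 2) * field.pixel_size
    yy, xx = np.meshgrid(np.arange(nwr), np.arange(nwc), indexing="ij")
    centers = np.stack([orig + xx * step, orig + yy * step], axis=-1)

    return OrderMap(S_values=S, window_mask=mask, window_cells=w, centers_um=centers)


def disorder_fraction(order_map: OrderMap, threshold: float = 0.5) -> float:
    """Fraction of unmasked windows whose local nematic order S < threshold."""
    s = order_map.S_values[order_map.window_mask]
    if s.size == 0:
        raise ValueError("all windows are masked")
    return float(np.mean(s < threshold))


def nematic_summary(
    field: OrientationField,
    window_cells: int = 4,
    S_threshold: float = 0.5,
    floor: float = 0.5,
) -> NematicSummary:
    """Convenience wrapper: eta_L and disorder fraction for one field."""
    curve = spatial_correlation(field)
    eta = nematic_length(curve, floor=floor)
    om = local_nematic_order(field, window_cells=window_cells)
    frac = disorder_fraction(om, threshold=S_threshold)
    return NematicSummary(
        nematic_length_um=eta,
        disorder_fraction=frac,
        threshold_used=S_threshold,
        parameters={"window_cells": window_cells, "fit_floor": floor},
    )
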