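"""Synthetic microscopy inputs with attached ground truth.

Every analysis input the pipeline consumes can be generated here with known
truth, emulating the statistical structure the analyses assume:

* swirly fiber-texture images with a controllable orientation correlation
  length (smooth random nematic field + fiber strokes rendered tangent to
  it);
* sets of polyline fiber traces organised into known bundles that converge
  on shared attachment foci, with generation-time guarantees on within- and
  between-bundle Hausdorff distances;
* 1D titin-like intensity profiles composed of periodic Gaussian-peak-train
  segments (sarcomere period about 2 µm), matched-variance noise stretches
  and gaps;
* laser-ablation recoil trajectories drawn from the asymptotic viscoelastic
  model plus Gaussian noise;
* 1D DAPI-like nuclei profiles with a known number of well-separated peaks.

All generators are pure functions of (parameters, seed): identical inputs
reproduce identical outputs. Each returns a :class:`SyntheticTruth` sidecar
recording the generator name, parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from myoscale.bundles import FiberTrace, FociSet, pairwise_hausdorff
from myoscale.morphometrics import LineProfile
from myoscale.periodicity import IntensityProfile
from myoscale.recoil import RecoilTrack, recoil_model

__all__ = [
    "SyntheticTruth",
    "ProfileSegment",
    "gen_orientation_image",
    "gen_trace_set",
    "gen_periodic_profile",
    "gen_recoil_tracks",
    "gen_nuclei_profile",
]


@dataclass
class SyntheticTruth:
    """Ground-truth sidecar attached to every generated dataset."""

    generator: str
    parameters: Dict[str, object]
    seed: int

    def as_dict(self) -> Dict[str, object]:
        return {"generator": self.generator, "seed": self.seed,
                "parameters": self.parameters}


# ---------------------------------------------------------------------------
# orientation textures


def sample_angle_field(
    shape: Tuple[int, int],
    correlation_length_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth random nematic angle field with tunable spatial correlation.

    A complex Gaussian white-noise field representing the doubled angle is
    low-pass filtered at ``correlation_length_px``; the angle field is half
    its argument, so theta varies smoothly and wraps correctly through the
    nematic identification theta ~ theta + pi. ``inf`` gives a uniform
    field at a random angle.
    """
    if np.isinf(correlation_length_px):
        theta0 = rng.uniform(-np.pi / 2, np.pi / 2)
        return np.full(shape, theta0)
    w = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    w = gaussian_filter(w.real, correlation_length_px) \
        + 1j * gaussian_filter(w.imag, correlation_length_px)
    return 0.5 * np.angle(w)


def _trace_streamline(
    ufield: np.ndarray,
    vfield: np.ndarray,
    start: np.ndarray,
    n_steps: int,
    step: float,
    shape: Tuple[int, int],
) -> np.ndarray:
    """Integrate a streamline tangent to a nematic director field.

    The field is given as the doubled-angle unit vectors (u, v); the sign
    of each step is chosen for continuity with the previous direction.
    Returns (n, 2) pixel positions (x, y_row); stops at the image border.
    """
    h, w = shape
    pos = start.astype(float).copy()
    prev = None
    pts = [pos.copy()]
    for _ in range(n_steps):
        iy = min(max(int(round(pos[1])), 0), h - 1)
        ix = min(max(int(round(pos[0])), 0), w - 1)
        theta = 0.5 * np.arctan2(vfield[iy, ix], ufield[iy, ix])
        d = np.array([np.cos(theta), -np.sin(theta)])  # y-axis points down rows
        if prev is not None and np.dot(d, prev) < 0:
            d = -d
        prev = d
        pos = pos + step * d
        if not (0 <= pos[0] < w - 1 and 0 <= pos[1] < h - 1):
            break
        pts.append(pos.copy())
    return np.array(pts)


def gen_orientation_image(
    shape: Tuple[int, int] = (512, 512),
    correlation_length_um: float = 100.0,
    n_fibers: int = 600,
    fiber_width_um: float = 2.0,
    fiber_length_um: float = 150.0,
    noise_sd: float = 0.05,
    pixel_size: float = 1.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Render a swirly fiber-texture image from a known analytic angle field.

    A smooth random nematic field at the requested correlation length is
    sampled; ``n_fibers`` curved strokes are integrated tangent to the
    field from random seeds and deposited onto the canvas; a Gaussian blur
    sets the fiber width and additive Gaussian noise the background level.

    Returns ``(image, angle_field, truth)`` where ``angle_field`` is the
    full-resolution analytic field (radians, [-pi/2, pi/2)) the strokes
    follow — the recovery target for the orientation module.
    """
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError("degenerate image shape")
    rng = np.random.default_rng(seed)
    lam_px = correlation_length_um / pixel_size
    theta = sample_angle_field(shape, lam_px, rng)
    ufield, vfield = np.cos(2 * theta), np.sin(2 * theta)

    canvas = np.zeros(shape)
    step = 0.5  # px
    n_steps = int(fiber_length_um / pixel_size / step)
    starts = np.column_stack([
        rng.uniform(1, w - 2, n_fibers),
        rng.uniform(1, h - 2, n_fibers),
    ])
    for s in starts:
        pts = _trace_streamline(ufield, vfield, s, n_steps, step, shape)
        iy = np.round(pts[:, 1]).astype(int)
        ix = np.round(pts[:, 0]).astype(int)
        np.add.at(canvas, (iy, ix), 1.0)

    img = gaussian_filter(canvas, fiber_width_um / pixel_size / 2)
    peak = img.max()
    if peak > 0:
        img = img / peak
    img = img + noise_sd * rng.standard_normal(shape)

    truth = SyntheticTruth(
        "orientation_image",
        {
            "shape": list(shape),
            "correlation_length_um": correlation_length_um,
            "n_fibers": n_fibers,
            "fiber_width_um": fiber_width_um,
            "fiber_length_um": fiber_length_um,
            "noise_sd": noise_sd,
            "pixel_size": pixel_size,
        },
        seed,
    )
    return img, theta, truth


# ---------------------------------------------------------------------------
# traced bundles


def gen_trace_set(
    n_bundles: int = 5,
    traces_per_bundle: int = 8,
    bundle_spread_um: float = 20.0,
    inter_bundle_distance_um: float = 150.0,
    trace_length_um: float = 500.0,
    jitter_um: float = 2.0,
    n_vertices: int = 50,
    seed: int = 0,
    max_retries: int = 5,
) -> Tuple[List[FiberTrace], Dict[str, int], FociSet, SyntheticTruth]:
    """Planted bundles of near-parallel jittered polylines with shared foci.

    Each bundle runs horizontally between two attachment foci; member
    traces bow away from the chord by individual amplitudes within
    ``bundle_spread_um`` plus smooth jitter, and meet exactly at the foci.
    Bundles are stacked with vertical spacing that guarantees

    * max within-bundle Hausdorff distance < 2 * bundle_spread_um, and
    * min between-bundle Hausdorff distance > inter_bundle_distance_um / 2,

    both verified at generation time on the resampled traces (retrying
    with fresh jitter, then raising, if violated).

    Returns ``(traces, planted_labels, foci, truth)``.
    """
    if inter_bundle_distance_um <= 2 * bundle_spread_um:
        raise ValueError("inter_bundle_distance must exceed 2 * bundle_spread")

    spacing = inter_bundle_distance_um + 2 * bundle_spread_um
    x = np.linspace(0.0, trace_length_um, n_vertices)
    bump = np.sin(np.pi * x / trace_length_um)  # vanishes at the foci

    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        traces: List[FiberTrace] = []
        labels: Dict[str, int] = {}
        foci_pts = []
        for b in range(n_bundles):
            y0 = b * spacing
            foci_pts += [(0.0, y0), (trace_length_um, y0)]
            for t in range(traces_per_bundle):
                amp = rng.uniform(-0.85, 0.85) * bundle_spread_um
                wig = gaussian_filter1d(rng.standard_normal(n_vertices), 4,
                                        mode="nearest")
                wig *= bump * jitter_um / max(np.abs(wig).max(), 1e-9)
                y = y0 + amp * bump + wig
                tid = f"b{b:02d}_t{t:02d}"
                traces.append(FiberTrace(tid, np.column_stack([x, y]),
                                         {"bundle": b}))
                labels[tid] = b

        d = pairwise_hausdorff(traces)
        planted = np.array([labels[t.trace_id] for t in traces])
        same = planted[:, None] == planted[None, :]
        off = ~np.eye(len(traces), dtype=bool)
        max_within = float(d[same & off].max()) if (same & off).any() else 0.0
        min_between = float(d[~same].min()) if (~same).any() else np.inf
        if max_within < 2 * bundle_spread_um and \
                min_between > inter_bundle_distance_um / 2:
            truth = SyntheticTruth(
                "trace_set",
                {
                    "n_bundles": n_bundles,
                    "traces_per_bundle": traces_per_bundle,
                    "bundle_spread_um": bundle_spread_um,
                    "inter_bundle_distance_um": inter_bundle_distance_um,
                    "trace_length_um": trace_length_um,
                    "jitter_um": jitter_um,
                    "max_within_hausdorff_um": max_within,
                    "min_between_hausdorff_um": min_between,
                },
                seed,
            )
            return traces, labels, FociSet(np.array(foci_pts)), truth
    raise RuntimeError("could not satisfy bundle separation guarantees")


# ---------------------------------------------------------------------------
# periodic intensity profiles


@dataclass
class ProfileSegment:
    """One stretch of a synthetic titin-like profile."""

    length_um: float
    kind: str = "periodic"  # "periodic" | "noise"
    period_um: float = 2.0
    amplitude: float = 1.0
    noise_sd: float = 0.1  # relative to amplitude

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("segment length must be positive")
        if self.kind not in ("periodic", "noise"):
            raise ValueError("kind must be 'periodic' or 'noise'")


def _peak_train(pos: np.ndarray, period: float, amplitude: float,
                peak_sigma: float) -> np.ndarray:
    centers = np.arange(period / 2, pos[-1] + period, period)
    sig = np.zeros_like(pos)
    for c in centers:
        sig += amplitude * np.exp(-0.5 * ((pos - c) / peak_sigma) ** 2)
    return sig


def gen_periodic_profile(
    segments: Sequence[Union[ProfileSegment, Tuple]],
    sample_um: float = 0.083,
    seed: int = 0,
) -> Tuple[IntensityProfile, np.ndarray, SyntheticTruth]:
    """Compose a 1D profile from periodic and noise segments.

    Periodic segments are Gaussian-peak trains (peak sigma = period / 8,
    the punctate Z-disc appearance of titin staining) plus white noise of
    ``noise_sd * amplitude``; noise segments are i.i.d. Gaussian samples
    matched to the mean and total variance of an equivalent periodic
    segment, so amplitude alone cannot separate the classes.

    Returns ``(profile, periodic_mask, truth)`` where the boolean mask
    marks ground-truth periodic samples.
    """
    segs = [s if isinstance(s, ProfileSegment) else ProfileSegment(*s)
            for s in segments]
    if sample_um <= 0:
        raise ValueError("sample_um must be positive")
    rng = np.random.default_rng(seed)

    chunks, masks = [], []
    for s in segs:
        n = max(int(round(s.length_um / sample_um)), 2)
        pos = np.arange(n) * sample_um
        template = _peak_train(pos, s.period_um, s.amplitude, s.period_um / 8)
        if s.kind == "periodic":
            sig = template + s.noise_sd * s.amplitude * rng.standard_normal(n)
            masks.append(np.ones(n, dtype=bool))
        else:
            var = template.var() + (s.noise_sd * s.amplitude) ** 2
            sig = template.mean() + np.sqrt(var) * rng.standard_normal(n)
            masks.append(np.zeros(n, dtype=bool))
        chunks.append(sig)

    intens = np.concatenate(chunks)
    mask = np.concatenate(masks)
    profile = IntensityProfile(
        positions=np.arange(len(intens)) * sample_um,
        intensities=intens,
        pixel_size=sample_um,
    )
    truth = SyntheticTruth(
        "periodic_profile",
        {
            "segments": [
                {"length_um": s.length_um, "kind": s.kind,
                 "period_um": s.period_um, "amplitude": s.amplitude,
                 "noise_sd": s.noise_sd}
                for s in segs
            ],
            "sample_um": sample_um,
        },
        seed,
    )
    return profile, mask, truth


# ---------------------------------------------------------------------------
# recoil tracks


def gen_recoil_tracks(
    n: int = 10,
    L0: float = 0.0,
    Lmax: float = 5.0,
    tau_s: float = 1.0,
    dt_s: float = 0.1,
    duration_s: float = 5.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    category: Optional[str] = None,
) -> Tuple[List[RecoilTrack], SyntheticTruth]:
    """Sample recoil tracks from the asymptotic viscoelastic model.

    ``L(t) = Lmax - (Lmax - L0) e^(-t/tau)`` plus i.i.d. Gaussian noise of
    ``noise_sd`` µm, clipped at zero separation. Defaults follow the
    5-second manual-tracking records of severed myofiber ends.
    """
    if tau_s <= 0 or duration_s <= dt_s:
        raise ValueError("need tau_s > 0 and duration_s > dt_s")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    clean = recoil_model(t, L0, Lmax, tau_s)
    tracks = []
    for k in range(n):
        L = np.clip(clean + noise_sd * rng.standard_normal(len(t)), 0.0, None)
        meta = {"category": category} if category else {}
        tracks.append(RecoilTrack(f"track{k:03d}", t, L, meta))
    truth = SyntheticTruth(
        "recoil_tracks",
        {"n": n, "L0": L0, "Lmax": Lmax, "tau_s": tau_s, "dt_s": dt_s,
         "duration_s": duration_s, "noise_sd": noise_sd},
        seed,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# nuclei profiles


def gen_nuclei_profile(
    length_um: float = 600.0,
    n_nuclei: int = 15,
    nucleus_sd_um: float = 3.0,
    amplitude: float = 1.0,
    background: float = 0.1,
    noise_sd: float = 0.1,
    min_gap_um: float = 15.0,
    sample_um: float = 0.5,
    psf_um: float = 1.0,
    seed: int = 0,
) -> Tuple[LineProfile, np.ndarray, SyntheticTruth]:
    """DAPI-like 1D profile with a known number of nuclei.

    Gaussian bumps of width ``nucleus_sd_um`` are placed with an enforced
    minimum centre-to-centre gap (exact spacing transform, no rejection),
    on a flat background with additive noise smoothed at the optical scale
    ``psf_um`` and rescaled to ``noise_sd``. The default noise level is
    typical of the high-contrast DAPI channel (SNR 10).

    Returns ``(profile, truth_positions_um, truth)``.
    """
    margin = max(2 * nucleus_sd_um, min_gap_um / 2)
    if n_nuclei * min_gap_um + 2 * margin >= length_um and n_nuclei > 0:
        raise ValueError("cannot pack that many nuclei at the requested gap")
    rng = np.random.default_rng(seed)

    free = length_um - 2 * margin - max(n_nuclei - 1, 0) * min_gap_um
    u = np.sort(rng.uniform(0.0, free, n_nuclei))
    centers = margin + u + np.arange(n_nuclei) * min_gap_um

    pos = np.arange(0.0, length_um, sample_um)
    sig = np.full_like(pos, background)
    for c in centers:
        sig += amplitude * np.exp(-0.5 * ((pos - c) / nucleus_sd_um) ** 2)

    noise = rng.standard_normal(len(pos))
    noise = gaussian_filter1d(noise, psf_um / sample_um)
    sd = noise.std()
    if sd > 0:
        noise *= noise_sd / sd
    profile = LineProfile(positions=pos, intensities=sig + noise,
                          mean_intensity=float((sig + noise).mean()))
    truth = SyntheticTruth(
        "nuclei_profile",
        {"length_um": length_um, "n_nuclei": n_nuclei,
         "nucleus_sd_um": nucleus_sd_um, "amplitude": amplitude,
         "background": background, "noise_sd": noise_sd,
         "min_gap_um": min_gap_um, "sample_um": sample_um, "psf_um": psf_um},
        seed,
    )
    return profile, centers, truth
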