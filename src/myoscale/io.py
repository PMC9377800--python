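"""Readers and writers for the pipeline's canonical formats.

Conventions, fixed across the package and printed in output headers:
pixel origin at the top-left corner, x to the right, y down, 0-based
indices; physical coordinates always in micrometres.

Formats: TIFF images/volumes (via :mod:`tifffile`); trace tables as CSV
``(trace_id, vertex_index, x_um, y_um)`` or JSON; ImageJ ``.roi``/``.zip``
polyline ROIs (minimal binary reader/writer for the documented layout);
recoil tracking tables as CSV ``(track_id, t_s, L_um[, category, exclude])``;
1D profiles as CSV ``(position_um, intensity)``; foci as CSV
``(x_um, y_um)``.
"""

from __future__ import annotations

import json
import struct
import zipfile
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from myoscale.bundles import BundleSet, FiberTrace, FociSet
from myoscale.periodicity import IntensityProfile, PeriodicityMap, StraightenPath
from myoscale.recoil import RecoilFit, RecoilTrack

__all__ = [
    "read_image",
    "read_traces",
    "write_traces",
    "read_imagej_roi",
    "write_imagej_roi",
    "read_foci",
    "read_recoil_tracks",
    "write_recoil_fits",
    "read_profile",
    "write_profile",
    "read_straighten_path",
    "write_bundleset",
    "write_periodicity_map",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"  # deterministic, round-trips float64 to 1e-9


# ---------------------------------------------------------------------------
# images


def read_image(
    path: str | Path,
    channel: Optional[int] = None,
    crop: Optional[tuple] = None,
) -> np.ndarray:
    """Read a TIFF image or volume, optionally selecting a channel and crop.

    ``crop`` is (cx, cy, width, height): a window centred at pixel
    (cx, cy) — e.g. the central region of a culture well, excluding edges
    and empty space.
    """
    arr = tifffile.imread(str(path))
    if channel is not None:
        if arr.ndim < 3:
            raise ValueError("image has no channel axis")
        # channel axis: the smallest axis, as in CYX / ZCYX exports
        ax = int(np.argmin(arr.shape[:-2]))
        arr = np.take(arr, channel, axis=ax)
    if crop is not None:
        cx, cy, w, h = crop
        x0, y0 = int(cx - w // 2), int(cy - h // 2)
        if x0 < 0 or y0 < 0 or y0 + h > arr.shape[-2] or x0 + w > arr.shape[-1]:
            raise ValueError("crop window exits the image")
        arr = arr[..., y0:y0 + h, x0:x0 + w]
    return arr


# ---------------------------------------------------------------------------
# trace tables


def read_traces(
    path: str | Path,
    format: Optional[str] = None,
    pixel_size: float = 1.0,
) -> List[FiberTrace]:
    """Read fiber traces from CSV, JSON or ImageJ .roi/.zip.

    The format is inferred from the suffix unless given. CSV columns:
    ``trace_id, vertex_index, x_um, y_um`` (vertex_index must increase
    within each trace). ``pixel_size`` converts ImageJ ROI pixel
    coordinates to µm; CSV/JSON are already in µm.
    """
    path = Path(path)
    fmt = format or {".csv": "csv", ".json": "json", ".roi": "imagej_roi",
                     ".zip": "imagej_roi"}.get(path.suffix.lower())
    if fmt == "csv":
        df = pd.read_csv(path)
        required = {"trace_id", "vertex_index", "x_um", "y_um"}
        if not required.issubset(df.columns):
            raise ValueError(f"trace CSV needs columns {sorted(required)}")
        traces = []
        for tid, g in df.groupby("trace_id", sort=True):
            vi = g["vertex_index"].to_numpy()
            if np.any(np.diff(vi) <= 0):
                rows = g.index[np.nonzero(np.diff(vi) <= 0)[0] + 1].tolist()
                raise ValueError(
                    f"trace {tid!r}: non-monotone vertex_index at rows {rows}")
            traces.append(FiberTrace(str(tid), g[["x_um", "y_um"]].to_numpy()))
        return traces
    if fmt == "json":
        data = json.loads(path.read_text())
        return [
            FiberTrace(str(t["trace_id"]), np.asarray(t["points"], float),
                       t.get("metadata", {}))
            for t in data["traces"]
        ]
    if fmt == "imagej_roi":
        return read_imagej_roi(path, pixel_size=pixel_size)
    raise ValueError(f"unknown trace format: {format or path.suffix}")


def write_traces(traces: Sequence[FiberTrace], path: str | Path) -> None:
    """Write traces as the canonical CSV table."""
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append((t.trace_id, i, x, y))
    df = pd.DataFrame(rows, columns=["trace_id", "vertex_index", "x_um", "y_um"])
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# ImageJ ROI (minimal: polyline-like types)

_ROI_POLY_TYPES = {0: "polygon", 4: "freeline", 5: "polyline", 7: "freehand"}


def _decode_roi(buf: bytes, name: str, pixel_size: float) -> FiberTrace:
    if buf[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = buf[6]
    if roi_type not in _ROI_POLY_TYPES:
        raise ValueError(f"unsupported ROI type {roi_type}")
    top, left, _, _ = struct.unpack(">4h", buf[8:16])
    n = struct.unpack(">h", buf[16:18])[0]
    xs = np.frombuffer(buf[64:64 + 2 * n], dtype=">i2").astype(float) + left
    ys = np.frombuffer(buf[64 + 2 * n:64 + 4 * n], dtype=">i2").astype(float) + top
    return FiberTrace(name, np.column_stack([xs, ys]) * pixel_size)


def read_imagej_roi(path: str | Path, pixel_size: float = 1.0) -> List[FiberTrace]:
    """Read polyline-type ImageJ .roi files (or a .zip of them), in µm."""
    path = Path(path)
    if path.suffix.lower() == ".zip":
        traces = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    traces.append(_decode_roi(zf.read(name),
                                              Path(name).stem, pixel_size))
        return traces
    return [_decode_roi(path.read_bytes(), path.stem, pixel_size)]


def write_imagej_roi(points_px: np.ndarray, path: str | Path,
                     roi_type: int = 5) -> None:
    """Write integer pixel vertices as a minimal ImageJ polyline .roi."""
    pts = np.asarray(points_px)
    xs = np.round(pts[:, 0]).astype(int)
    ys = np.round(pts[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, int(ys.max()), int(xs.max()))
    struct.pack_into(">h", header, 16, len(pts))
    body = (xs - left).astype(">i2").tobytes() + (ys - top).astype(">i2").tobytes()
    Path(path).write_bytes(bytes(header) + body)


# ---------------------------------------------------------------------------
# foci, recoil, profiles, paths


def read_foci(path: str | Path) -> FociSet:
    """Read attachment foci from CSV (x_um, y_um)."""
    df = pd.read_csv(path)
    return FociSet(df[["x_um", "y_um"]].to_numpy())


def read_recoil_tracks(path: str | Path) -> List[RecoilTrack]:
    """Read recoil tracking tables: track_id, t_s, L_um[, category, exclude]."""
    df = pd.read_csv(path)
    required = {"track_id", "t_s", "L_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"recoil CSV needs columns {sorted(required)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        meta: Dict[str, object] = {}
        if "category" in g.columns:
            meta["category"] = str(g["category"].iloc[0])
        if "exclude" in g.columns:
            meta["exclude"] = bool(g["exclude"].iloc[0])
        tracks.append(RecoilTrack(str(tid), g["t_s"].to_numpy(),
                                  g["L_um"].to_numpy(), meta))
    return tracks


def write_recoil_fits(fits: Sequence[RecoilFit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "track_id": f.track_id, "v0_um_per_s": f.v0_linear,
                "L0_um": f.L0, "Lmax_um": f.Lmax, "tau_s": f.tau,
                "v0_model_um_per_s": f.v0_model, "rss": f.rss,
                "converged": f.converged, "reliable": f.reliable,
                "category": f.category,
            }
            for f in fits
        ]
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_profile(path: str | Path) -> IntensityProfile:
    """Read a pre-extracted 1D profile CSV (position_um, intensity)."""
    df = pd.read_csv(path)
    pos = df["position_um"].to_numpy()
    return IntensityProfile(pos, df["intensity"].to_numpy(),
                            float(np.mean(np.diff(pos))))


def write_profile(profile: IntensityProfile, path: str | Path) -> None:
    pd.DataFrame({"position_um": profile.positions,
                  "intensity": profile.intensities}
                 ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_straighten_path(path: str | Path) -> StraightenPath:
    """Read a straightening path JSON: xy (and optional xz) vertices in px."""
    data = json.loads(Path(path).read_text())
    return StraightenPath(
        xy_vertices=np.asarray(data["xy_vertices"], float),
        xz_vertices=(np.asarray(data["xz_vertices"], float)
                     if data.get("xz_vertices") else None),
        half_width=int(data.get("half_width", 2)),
    )


# ---------------------------------------------------------------------------
# result writers


def write_bundleset(bs: BundleSet, out_dir: str | Path) -> None:
    """Write cluster assignments and per-bundle areas as CSV."""
    out = Path(out_dir)
    pd.DataFrame(
        sorted(bs.assignments.items()), columns=["trace_id", "bundle"]
    ).to_csv(out / "bundle_assignments.csv", index=False)
    pd.DataFrame(
        sorted(bs.areas_um2.items()), columns=["bundle", "area_um2"]
    ).to_csv(out / "bundle_areas.csv", index=False, float_format=FLOAT_FORMAT)


def write_periodicity_map(pmap: PeriodicityMap, out_dir: str | Path) -> None:
    """Write the per-window map and classified regions as CSV."""
    out = Path(out_dir)
    pd.DataFrame({
        "center_um": pmap.window_centers_um,
        "peak_lag_um": pmap.peak_lag_um,
        "prominence": pmap.prominence,
        "periodic": pmap.periodic_flags.astype(int),
    }).to_csv(out / "periodicity_windows.csv", index=False,
              float_format=FLOAT_FORMAT)
    if pmap.regions is not None:
        pd.DataFrame(pmap.regions, columns=["start_um", "end_um"]).to_csv(
            out / "periodic_regions.csv", index=False, float_format=FLOAT_FORMAT)
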