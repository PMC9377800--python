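"""Laser-ablation recoil quantification.

After a fiber is severed, the distance L(t) between the severed ends grows
and saturates. Two readouts quantify the pre-cut mechanics:

* the initial recoil velocity ``v0`` — the ordinary-least-squares slope of
  L against t over the first second — a proxy for pre-cut tension;
* the viscoelastic relaxation time ``tau`` from the asymptotic model

      L(t) = Lmax - (Lmax - L0) * exp(-t / tau)

  where ``L0`` is the separation at t = 0 and ``Lmax`` the asymptote.
  ``tau`` is the ratio of the material viscosity to the elastic modulus.

End tracking is manual upstream; this module ingests tracking tables only.
Actively contracting fibers are excluded by the caller via the ``exclude``
metadata flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RecoilTrack",
    "RecoilFit",
    "recoil_model",
    "fit_initial_velocity",
    "fit_viscoelastic",
    "fit_mean_curve",
    "summarize_fits",
]


def recoil_model(t: np.ndarray, L0: float, Lmax: float, tau: float) -> np.ndarray:
    """Asymptotic viscoelastic recoil: L(t) = Lmax - (Lmax - L0) e^(-t/tau)."""
    return Lmax - (Lmax - L0) * np.exp(-np.asarray(t, float) / tau)


@dataclass
class RecoilTrack:
    """Severed-end separation vs. time for one ablation.

    ``times`` are seconds from ablation (t = 0 at the first post-cut
    frame); ``separations`` in µm.
    """

    track_id: str
    times: np.ndarray
    separations: np.ndarray
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.separations = np.asarray(self.separations, dtype=float)
        if self.times.shape != self.separations.shape or self.times.ndim != 1:
            raise ValueError("times and separations must be equal-length 1D")
        if len(self.times) < 4:
            raise ValueError("track needs >= 4 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.separations < 0) or not np.all(np.isfinite(self.separations)):
            raise ValueError("separations must be finite and >= 0")

    @property
    def category(self) -> Optional[str]:
        return self.metadata.get("category")

    @property
    def excluded(self) -> bool:
        return bool(self.metadata.get("exclude", False))


@dataclass
class RecoilFit:
    """Fitted recoil parameters for one track."""

    track_id: str
    v0_linear: Optional[float] = None  # first-second OLS slope, µm/s
    L0: Optional[float] = None
    Lmax: Optional[float] = None
    tau: Optional[float] = None
    v0_model: Optional[float] = None  # (Lmax - L0)/tau, the model's initial slope
    rss: Optional[float] = None
    converged: bool = False
    reliable: bool = False  # converged and tau within the track duration
    category: Optional[str] = None


def fit_initial_velocity(track: RecoilTrack, t_window: float = 1.0) -> float:
    """Initial recoil velocity: OLS slope of L vs t over t <= t_window."""
    sel = track.times <= t_window
    if sel.sum() < 2:
        raise ValueError("need >= 2 samples within the fitting window")
    slope, _ = np.polyfit(track.times[sel], track.separations[sel], 1)
    return float(slope)


def _initial_guess(t: np.ndarray, L: np.ndarray) -> tuple:
    L0, Lmax = L[0], L[-1]
    target = L0 + 0.63 * (Lmax - L0)
    tau = None
    if Lmax > L0:
        above = np.nonzero(L >= target)[0]
        if len(above) and above[0] > 0:
            tau = float(t[above[0]])
    if tau is None or tau <= 0:
        tau = float((t[-1] - t[0]) / 2) or 1.0
    return float(L0), float(Lmax), tau


def fit_viscoelastic(track: RecoilTrack, t_window: float = 1.0) -> RecoilFit:
    """Fit the asymptotic recoil model to one track.

    Bounded nonlinear least squares over (L0, dL = Lmax - L0 >= 0,
    tau > 0) with a fixed, data-driven initialisation: L0 from the first
    sample, Lmax from the last, tau from the time at which L crosses
    L0 + 0.63 (Lmax - L0) (fallback: half the track duration). Reports the
    residual sum of squares, a convergence flag, a reliability flag
    (converged and tau not exceeding the record duration — a tau beyond
    the record means no plateau was observed) and the model-implied
    initial velocity (Lmax - L0)/tau, alongside the first-second linear
    v0.
    """
    t, L = track.times, track.separations
    fit = RecoilFit(track_id=track.track_id, category=track.category)
    try:
        fit.v0_linear = fit_initial_velocity(track, t_window)
    except ValueError:
        pass
    if np.ptp(L) == 0:
        return fit  # constant track: unidentifiable

    L0g, Lmaxg, taug = _initial_guess(t, L)

    def resid(p):
        L0, dL, tau = p
        return recoil_model(t, L0, L0 + dL, tau) - L

    duration = float(t[-1] - t[0])
    res = least_squares(
        resid,
        x0=[L0g, max(Lmaxg - L0g, 1e-6), taug],
        bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        method="trf",
    )
    if not res.success:
        return fit
    L0, dL, tau = res.x
    fit.L0, fit.Lmax, fit.tau = float(L0), float(L0 + dL), float(tau)
    fit.v0_model = float(dL / tau)
    fit.rss = float(np.sum(res.fun**2))
    fit.converged = True
    fit.reliable = tau <= duration
    return fit


def fit_mean_curve(
    tracks: Sequence[RecoilTrack], t_window: float = 1.0
) -> RecoilFit:
    """Fit the model to the across-track mean curve (common time base).

    Tracks are interpolated onto the time grid of the first track before
    averaging; use when the per-track curves are too noisy individually.
    """
    if not tracks:
        raise ValueError("need at least one track")
    t0 = tracks[0].times
    mean_L = np.mean(
        [np.interp(t0, tr.times, tr.separations) for tr in tracks], axis=0
    )
    mean_track = RecoilTrack("mean", t0, mean_L, {"category": tracks[0].category})
    fit = fit_viscoelastic(mean_track, t_window)
    fit.track_id = "mean"
    return fit


def summarize_fits(fits: Sequence[RecoilFit]) -> Dict[str, Dict[str, float]]:
    """Per-category summaries of v0 and tau: mean±sd and median±IQR."""
    by_cat: Dict[str, List[RecoilFit]] = {}
    for f in fits:
        by_cat.setdefault(f.category or "all", []).append(f)
    out: Dict[str, Dict[str, float]] = {}
    for cat, fs in sorted(by_cat.items()):
        v0 = np.array([f.v0_linear for f in fs if f.v0_linear is not None])
        tau = np.array([f.tau for f in fs if f.converged])
        stats: Dict[str, float] = {"n_tracks": len(fs), "n_converged": int(len(tau))}
        for name, vals in (("v0", v0), ("tau", tau)):
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                stats.update({
                    f"{name}_mean": float(vals.mean()),
                    f"{name}_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    f"{name}_median": float(med),
                    f"{name}_iqr": float(q3 - q1),
                })
        out[cat] = stats
    return out
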