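"""Mechanics from ferrofluid-droplet observations.

An injected ferrofluid droplet trapped in the neural-tube lumen relaxes
toward a sphere under its own surface tension; the droplet-lumen interface
curvature reports the pressure the droplet exerts on the wall (spherical-cap
Laplace law, 2*gamma/r), and the hours-long decay of the droplet aspect
ratio reports the effective viscosity of the surrounding tissue.  This
module extracts those quantities from time series of droplet contours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "DropletSeries", "capsule_contour",
    "cap_curvature", "laplace_pressure", "aspect_ratio",
    "aspect_ratio_series", "fit_rounding_timescale",
    "roof_thickness_at_droplet",
]


# ---------------------------------------------------------------------------
# geometry helpers

def capsule_contour(r_um: float, L_um: float, n_points: int = 200) -> np.ndarray:
    """Closed sphero-cylinder outline: caps of radius r, total length L.

    Major axis along x, centred at the origin; points ordered
    counter-clockwise.  ``L >= 2 r``; L == 2 r gives a circle.
    """
    if r_um <= 0:
        raise ValueError("cap radius must be positive")
    if L_um < 2 * r_um - 1e-9:
        raise ValueError("capsule length must be at least the cap diameter")
    half_c = max(L_um / 2.0 - r_um, 0.0)
    # allocate points proportionally to arc length so the outline is evenly
    # sampled whatever the elongation (degenerate sides get no points)
    cap_arc = math.pi * r_um
    perimeter = 2 * cap_arc + 4 * half_c
    n_cap = max(int(round(n_points * cap_arc / perimeter)), 8)
    n_side = max(int(round(n_points * 2 * half_c / perimeter)), 0)
    th_r = np.linspace(-math.pi / 2, math.pi / 2, n_cap)
    right = np.column_stack([half_c + r_um * np.cos(th_r), r_um * np.sin(th_r)])
    th_l = np.linspace(math.pi / 2, 3 * math.pi / 2, n_cap)
    left = np.column_stack([-half_c + r_um * np.cos(th_l), r_um * np.sin(th_l)])
    parts = [right]
    if n_side:
        parts.append(np.column_stack([
            np.linspace(half_c, -half_c, n_side + 2)[1:-1],
            np.full(n_side, r_um)]))
    parts.append(left)
    if n_side:
        parts.append(np.column_stack([
            np.linspace(-half_c, half_c, n_side + 2)[1:-1],
            np.full(n_side, -r_um)]))
    return np.vstack(parts)


def _closed_arc_lengths(contour: np.ndarray) -> np.ndarray:
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def _polygon_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# container

@dataclass
class DropletSeries:
    """Time-stamped droplet contours with per-frame derived shape metrics."""

    times_h: np.ndarray
    contours: list                      # list of (N, 2) arrays, um
    aspect_ratio: np.ndarray
    cap_radius_um: np.ndarray
    length_um: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if len(self.contours) != self.times_h.size:
            raise ValueError("one contour per frame required")

    @classmethod
    def from_arrays(cls, times_h, contours, aspect_ratio, cap_radius_um,
                    length_um, meta=None) -> "DropletSeries":
        return cls(times_h=np.asarray(times_h, float), contours=list(contours),
                   aspect_ratio=np.asarray(aspect_ratio, float),
                   cap_radius_um=np.asarray(cap_radius_um, float),
                   length_um=np.asarray(length_um, float), meta=dict(meta or {}))

    @classmethod
    def from_contours(cls, times_h, contours, meta=None) -> "DropletSeries":
        """Build a series from raw contours, deriving metrics per frame."""
        times_h = np.asarray(times_h, dtype=float)
        asp, rcap, length = [], [], []
        keep_t, keep_c = [], []
        for t, c in zip(times_h, contours):
            c = np.asarray(c, dtype=float)
            if abs(_polygon_area(c)) < 1e-9:
                warnings.warn(f"degenerate (zero-area) contour at t={t:g} h skipped")
                continue
            a = aspect_ratio(c)
            r, _ = cap_curvature(c, end="anterior")
            L = _major_axis_length(c)
            keep_t.append(t)
            keep_c.append(c)
            asp.append(a)
            rcap.append(r)
            length.append(L)
        return cls(times_h=np.asarray(keep_t), contours=keep_c,
                   aspect_ratio=np.asarray(asp),
                   cap_radius_um=np.asarray(rcap),
                   length_um=np.asarray(length), meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# per-contour operations

def _principal_axis(contour: np.ndarray):
    c = contour - contour.mean(axis=0)
    cov = c.T @ c / c.shape[0]
    w, v = np.linalg.eigh(cov)
    e1 = v[:, np.argmax(w)]
    return e1 / np.hypot(*e1)


def _major_axis_length(contour: np.ndarray) -> float:
    e1 = _principal_axis(contour)
    proj = contour @ e1
    return float(proj.max() - proj.min())


def aspect_ratio(contour: np.ndarray) -> float:
    """Length along the major principal axis over the maximum perpendicular
    width, i.e. L / (2 R_max); >= 1 for convex capsules by construction."""
    contour = np.asarray(contour, dtype=float)
    e1 = _principal_axis(contour)
    e2 = np.array([-e1[1], e1[0]])
    proj1 = contour @ e1
    proj2 = contour @ e2
    width = proj2.max() - proj2.min()
    if width <= 0:
        raise ValueError("degenerate contour: zero width")
    return float((proj1.max() - proj1.min()) / width)


def aspect_ratio_series(series: DropletSeries) -> np.ndarray:
    """Per-frame aspect ratios recomputed from the stored contours."""
    return np.asarray([aspect_ratio(c) for c in series.contours])


def _fit_circle(points: np.ndarray):
    """Algebraic (Kasa) least-squares circle fit; returns (cx, cy, r, rms).

    Collinear point sets have zero curvature: r = inf with an inf rms flag.
    """
    centred = points - points.mean(axis=0)
    w = np.linalg.eigvalsh(centred.T @ centred / points.shape[0])
    if w[0] <= 1e-12 * w[1]:
        return math.nan, math.nan, math.inf, math.inf
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    try:
        sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return math.nan, math.nan, math.inf, math.inf
    if rank < 3:
        return math.nan, math.nan, math.inf, math.inf
    cx, cy, c = sol
    r2 = c + cx ** 2 + cy ** 2
    if r2 <= 0:
        return math.nan, math.nan, math.inf, math.inf
    r = math.sqrt(r2)
    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
    return float(cx), float(cy), r, rms


def cap_curvature(contour: np.ndarray, end: str = "anterior",
                  arc_fraction: float = 0.25):
    """Least-squares circle fit to one end cap of the droplet contour.

    The cap arc is the set of points within ``arc_fraction`` of the total
    contour length (centred) nearest the end extremum along the major axis;
    ``end='anterior'`` selects the maximum-projection end, ``'posterior'``
    the minimum.  Returns ``(r_um, fit_rms_um)``; collinear cap points give
    ``r = inf`` (zero curvature) with an infinite rms flag.
    """
    contour = np.asarray(contour, dtype=float)
    e1 = _principal_axis(contour)
    proj = contour @ e1
    idx_ext = int(np.argmax(proj) if end == "anterior" else np.argmin(proj))
    if end not in ("anterior", "posterior"):
        raise ValueError("end must be 'anterior' or 'posterior'")

    seg = _closed_arc_lengths(contour)
    perimeter = float(seg.sum())
    # arc distance from the extremum, walking both directions
    n = contour.shape[0]
    # cumulative distance forward from extremum
    fwd = np.concatenate([[0.0], np.cumsum(np.roll(seg, -idx_ext))])[:n]
    bwd = perimeter - fwd
    dist = np.minimum(fwd, bwd)
    sel_rolled = dist <= arc_fraction * perimeter / 2.0
    sel = np.roll(sel_rolled, idx_ext)
    pts = contour[sel]
    if pts.shape[0] < 8:
        raise ValueError(f"cap arc has {pts.shape[0]} points (< 8)")
    _, _, r, rms = _fit_circle(pts)
    return r, rms


def laplace_pressure(r_um: float, gamma_N_m: float) -> float:
    """Spherical-cap Laplace pressure jump 2*gamma/r in Pa."""
    if r_um <= 0:
        raise ValueError("cap radius must be positive")
    return 2.0 * gamma_N_m / (r_um * 1e-6)


# ---------------------------------------------------------------------------
# relaxation fit

def fit_rounding_timescale(series: DropletSeries) -> dict:
    """Exponential fit A(t) = A_inf + (A_0 - A_inf) exp(-t / tau).

    tau (hours) initialises the simulation-based viscosity estimate.
    Requires >= 5 frames; series spanning less than one relaxation e-fold
    are flagged ``lower_bound`` (tau is then only a lower limit).  A series
    whose aspect ratio increases over time violates the relaxation model
    and is refused.
    """
    t = np.asarray(series.times_h, dtype=float)
    A = np.asarray(series.aspect_ratio, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 frames for the rounding fit")

    slope = np.polyfit(t, A, 1)[0]
    spread = max(np.std(A), 1e-12)
    if slope * (t[-1] - t[0]) > 0.1 * spread and A[-1] > A[0]:
        raise ValueError("aspect ratio increases over time; rounding model violated")

    A0, Aend = A[0], A[-1]
    if abs(A0 - Aend) < 1e-6:
        return {"tau_h": math.inf, "A_inf": float(Aend), "A_0": float(A0),
                "residual_rms": 0.0, "lower_bound": True}

    tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)

    def model(tt, tau, A_inf, A_0):
        return A_inf + (A_0 - A_inf) * np.exp(-tt / tau)

    p0 = [tau0, max(min(A), 1.0), A0]
    lo = [1e-6, 0.0, 0.0]
    hi = [1e6, np.inf, np.inf]
    popt, _ = optimize.curve_fit(model, t, A, p0=p0, bounds=(lo, hi),
                                 maxfev=20000)
    tau, A_inf, A_0 = (float(v) for v in popt)
    resid = model(t, *popt) - A
    rms = float(np.sqrt(np.mean(resid ** 2)))
    lower_bound = (t[-1] - t[0]) < tau
    return {"tau_h": tau, "A_inf": A_inf, "A_0": A_0,
            "residual_rms": rms, "lower_bound": lower_bound}


# ---------------------------------------------------------------------------
# roof thickness at droplet site

def roof_thickness_at_droplet(section, window_um: float) -> float:
    """Minimum dorsal thickness within an arc window around the dorsal midpoint.

    Operationalises "thickness at the point of maximum roof deformation":
    the droplet dimples the roof, so the deformed site is the thinnest
    dorsal sample.  ``window_um = 0`` degenerates to the thickness exactly
    at the dorsal midpoint.  ``section`` is a
    :class:`~neurotube.tissue_shape.CrossSectionContours`.
    """
    from .tissue_shape import thickness_profile

    profile = thickness_profile(section)
    s = profile.s_raw_um
    th = profile.thickness_um
    if window_um < 0:
        raise ValueError("window must be non-negative")
    max_s = float(s.max())
    if window_um > max_s:
        warnings.warn(f"window {window_um:g} um exceeds profile extent "
                      f"{max_s:g} um; clipped")
        window_um = max_s
    if window_um == 0:
        return float(th[np.argmin(s)])
    sel = s <= window_um
    return float(np.min(th[sel]))
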