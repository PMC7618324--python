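"""Quantification of neural-tube cross-section shape.

Implements the study's measurement conventions: circumferential tissue
thickness profiles normalised so the dorsal midpoint sits at s = 0 and the
ventral midpoint at s = 1, a 4th-degree polynomial "average" profile across
specimens, dorsal-roof summary metrics (mean thickness over 100 or 300 um
windows, single-cell-thick roof length), apical intensity binning, and the
two-group statistics used throughout.

Thickness is measured from each inner-contour sample along the local
outward normal to the nearest intersection with the outer contour ("radial"
thickness, read as locally radial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .defaults import SINGLE_CELL_THICKNESS_UM
from .stats import two_group_test

__all__ = [
    "CrossSectionContours", "ThicknessProfile", "IntensityTrace",
    "thickness_profile", "normalise_and_average", "roof_metrics",
    "apical_intensity_bins", "two_group_test",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class CrossSectionContours:
    """Inner (lumen) and outer (basal) boundary contours of one cross-section.

    Contours are ordered counter-clockwise; index 0 of each contour is the
    dorsal midpoint (12 o'clock).  Units: micrometres.
    """

    inner: np.ndarray
    outer: np.ndarray
    dorsal_index_inner: int = 0
    dorsal_index_outer: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        for name in ("inner", "outer"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 8:
                raise ValueError(f"{name} contour must be (n>=8, 2)")
        inner_poly = Polygon(self.inner)
        outer_poly = Polygon(self.outer)
        if not outer_poly.is_valid:
            raise ValueError("outer contour is self-intersecting")
        if not inner_poly.is_valid:
            raise ValueError("inner contour is self-intersecting")
        if not outer_poly.contains(inner_poly):
            raise ValueError("inner contour must lie strictly inside the outer")


@dataclass
class ThicknessProfile:
    """Arc-position -> thickness map, raw (um) and dorsoventrally normalised."""

    s_raw_um: np.ndarray
    s_norm: np.ndarray
    thickness_um: np.ndarray
    side: np.ndarray          # 'left' | 'right'
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s_raw_um = np.asarray(self.s_raw_um, dtype=float)
        self.s_norm = np.asarray(self.s_norm, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        self.side = np.asarray(self.side, dtype=object)
        if np.any(self.thickness_um <= 0):
            raise ValueError("thickness must be positive")
        if np.any((self.s_norm < 0) | (self.s_norm > 1 + 1e-9)):
            raise ValueError("normalised arc position must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_raw_um": self.s_raw_um, "s_norm": self.s_norm,
            "thickness_um": self.thickness_um, "side": self.side,
        })

    def side_profile(self, side: str):
        m = self.side == side
        order = np.argsort(self.s_norm[m])
        return self.s_norm[m][order], self.thickness_um[m][order]


@dataclass
class IntensityTrace:
    """Apical-surface intensity versus arc distance from the dorsal midpoint."""

    position_um: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position_um.size != self.intensity.size or self.position_um.size == 0:
            raise ValueError("positions and intensities must be equal, non-empty")
        if np.any(np.diff(self.position_um) <= 0):
            raise ValueError("positions must be strictly increasing")

    def normalised(self, mode: str = "max") -> np.ndarray:
        if mode == "max":
            denom = float(np.max(self.intensity))
        elif mode == "mean":
            denom = float(np.mean(self.intensity))
        else:
            raise ValueError("mode must be 'max' or 'mean'")
        if denom <= 0:
            raise ValueError("cannot normalise a non-positive trace")
        return self.intensity / denom


# ---------------------------------------------------------------------------
# thickness profile

def _cumulative_arc(points: np.ndarray) -> np.ndarray:
    d = np.diff(points, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])


def _interp_along(points: np.ndarray, arc: np.ndarray, s: np.ndarray) -> np.ndarray:
    x = np.interp(s, arc, points[:, 0])
    y = np.interp(s, arc, points[:, 1])
    return np.column_stack([x, y])


def thickness_profile(section: CrossSectionContours, n_samples: int = 100) -> ThicknessProfile:
    """Thickness along the lumen circumference, both sides of the dorsal midpoint.

    At ``n_samples`` equally spaced inner-contour arc positions per side
    (from the dorsal midpoint to the ventral midpoint, defined as the point
    half the inner perimeter away), the thickness is the distance from the
    inner point along the local outward normal to the nearest intersection
    with the outer contour.  Samples whose normal misses the outer contour
    are dropped with a warning; a profile losing more than 10% of its
    samples is refused.
    """
    inner = np.roll(section.inner, -section.dorsal_index_inner, axis=0)
    inner_closed = np.vstack([inner, inner[:1]])
    arc = _cumulative_arc(inner_closed)
    perimeter = float(arc[-1])
    half = perimeter / 2.0

    outer_ring = LineString(np.vstack([section.outer, section.outer[:1]]))
    # ray length safely beyond any wall thickness
    bbox = section.outer.max(axis=0) - section.outer.min(axis=0)
    ray_len = 2.0 * float(np.hypot(*bbox))

    rows = []
    n_dropped = 0
    eps = perimeter * 1e-6
    for side, direction in (("right", +1), ("left", -1)):
        s_vals = np.linspace(0.0, half, n_samples)
        s_along = s_vals if direction > 0 else (perimeter - s_vals) % perimeter
        pts = _interp_along(inner_closed, arc, s_along)
        # local tangents by central differences on arc position
        p_fwd = _interp_along(inner_closed, arc, (s_along + eps) % perimeter)
        p_bwd = _interp_along(inner_closed, arc, (s_along - eps) % perimeter)
        tan = p_fwd - p_bwd
        norm = np.hypot(tan[:, 0], tan[:, 1])
        tan /= norm[:, None]
        # CCW contour: interior on the left of travel -> outward normal is
        # the tangent rotated -90 degrees
        normals = np.column_stack([tan[:, 1], -tan[:, 0]])
        for s_raw, p, nvec in zip(s_vals, pts, normals):
            ray = LineString([p, p + ray_len * nvec])
            hit = ray.intersection(outer_ring)
            if hit.is_empty:
                n_dropped += 1
                continue
            dist = hit.distance(Point(p)) if hit.geom_type == "Point" else (
                min(Point(p).distance(g) for g in getattr(hit, "geoms", [hit])))
            rows.append((s_raw, s_raw / half, dist, side))
    if n_dropped:
        warnings.warn(f"{n_dropped} thickness samples dropped (normal missed "
                      "the outer contour)")
        if n_dropped > 0.1 * 2 * n_samples:
            raise ValueError("more than 10% of thickness samples dropped; "
                             "profile refused (defective contours?)")

    rows = np.array(rows, dtype=object)
    return ThicknessProfile(
        s_raw_um=rows[:, 0].astype(float),
        s_norm=rows[:, 1].astype(float),
        thickness_um=rows[:, 2].astype(float),
        side=rows[:, 3],
        meta=dict(section.meta),
    )


# ---------------------------------------------------------------------------
# averaging across specimens

def normalise_and_average(profiles, grid_n: int = 101, poly_degree: int = 4) -> dict:
    """Pooled mean profile and 4th-degree polynomial "average" profile.

    Each profile (both sides pooled) is resampled onto a common normalised
    grid s in [0, 1]; the polynomial is fitted by least squares to the
    pooled raw samples of all profiles.  Profiles with fewer than 5 samples
    are excluded with a warning.

    Returns ``{"s_grid", "mean_profile_um", "poly_coeffs"}`` with
    ``poly_coeffs`` in ascending-power order (numpy.polynomial convention).
    """
    profiles = list(profiles)
    usable = []
    for i, p in enumerate(profiles):
        if p.s_norm.size < 5:
            warnings.warn(f"profile {i} has {p.s_norm.size} samples (< 5); excluded")
            continue
        usable.append(p)
    if not usable:
        raise ValueError("no usable profiles")

    s_grid = np.linspace(0.0, 1.0, grid_n)
    resampled = []
    pooled_s, pooled_th = [], []
    for p in usable:
        per_side = []
        for side in ("left", "right"):
            s, th = p.side_profile(side)
            if s.size >= 2:
                per_side.append(np.interp(s_grid, s, th))
        resampled.append(np.mean(per_side, axis=0))
        pooled_s.append(p.s_norm)
        pooled_th.append(p.thickness_um)
    mean_profile = np.mean(resampled, axis=0)

    pooled_s = np.concatenate(pooled_s)
    pooled_th = np.concatenate(pooled_th)
    coeffs = np.polynomial.polynomial.polyfit(pooled_s, pooled_th, poly_degree)
    return {"s_grid": s_grid, "mean_profile_um": mean_profile,
            "poly_coeffs": coeffs}


# ---------------------------------------------------------------------------
# roof metrics

def roof_metrics(profile: ThicknessProfile, window_um: float,
                 single_cell_thickness_um: float = SINGLE_CELL_THICKNESS_UM) -> dict:
    """Dorsal-roof summary metrics.

    ``mean_roof_thickness_um``: mean thickness over raw arc distance
    [0, window] from the dorsal midpoint, averaged over both sides.
    ``roof_length_um``: total arc length (both sides) of the contiguous
    single-cell-thick roof, i.e. up to the last contiguous sample at or
    below ``single_cell_thickness_um`` starting from the dorsal midpoint.
    """
    if window_um < 0:
        raise ValueError("window must be non-negative")
    out = {}
    means, lengths = [], []
    for side in ("left", "right"):
        m = profile.side == side
        s = profile.s_raw_um[m]
        th = profile.thickness_um[m]
        if s.size == 0:
            continue
        order = np.argsort(s)
        s, th = s[order], th[order]
        in_win = s <= window_um
        if np.any(in_win):
            means.append(float(np.mean(th[in_win])))
        # contiguous run from the dorsal midpoint
        below = th <= single_cell_thickness_um
        if not below[0]:
            lengths.append(0.0)
        else:
            stop = np.argmax(~below) if np.any(~below) else below.size
            lengths.append(float(s[stop - 1]))
    if not means:
        out["mean_roof_thickness_um"] = None
        out["reason"] = "window not covered by profile"
    else:
        out["mean_roof_thickness_um"] = float(np.mean(means))
    out["roof_length_um"] = float(np.sum(lengths)) if lengths else None
    return out


# ---------------------------------------------------------------------------
# apical intensity

def apical_intensity_bins(trace: IntensityTrace, n_bins: int,
                          normalisation: str = "max") -> np.ndarray:
    """Mean normalised intensity in equal-arc-length bins from the dorsal end.

    Bin means are trapezoidal integral means of the piecewise-linear trace,
    so a linear ramp 0 -> 1 split into two bins gives exactly (0.25, 0.75).
    """
    if n_bins not in (2, 3):
        raise ValueError("n_bins must be 2 or 3")
    pos = trace.position_um
    val = trace.normalised(mode=normalisation)
    edges = np.linspace(pos[0], pos[-1], n_bins + 1)
    # any empty interior would mean the trace is too sparse to bin
    counts, _ = np.histogram(pos, bins=edges)
    if np.any(counts == 0):
        raise ValueError("a bin contains no samples; trace too sparse")
    means = np.empty(n_bins)
    for i in range(n_bins):
        a, b = edges[i], edges[i + 1]
        grid = np.unique(np.concatenate([[a, b], pos[(pos >= a) & (pos <= b)]]))
        vals = np.interp(grid, pos, val)
        means[i] = np.trapezoid(vals, grid) / (b - a)
    return means
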