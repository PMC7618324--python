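"""Synthetic inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here: AFM creep
experiments from a power-law material under the measured force-ramp
protocol, neural-tube cross-section contours (constant annulus, eccentric
annulus, dorsally thinned), ferrofluid-droplet rounding series from the
Maxwell tube forward model, and small paired cohorts with group effects in
fluidity — mirroring the study's structure (hindbrain vs spinal cord within
the same embryo, n of a few to nine, additive Gaussian measurement noise).

Every generator is a pure function of its arguments and seed: the same seed
gives bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import afm_rheology, tube_mechanics
from .afm_rheology import CreepRecord, RampFit, hereditary_creep_oracle
from .defaults import AFM_PROTOCOL, T0_S
from .droplet_analysis import DropletSeries
from .tissue_shape import CrossSectionContours
from .tube_mechanics import Material, MaterialParams, TubeState

__all__ = [
    "GroundTruth", "CreepProtocol", "gen_creep_experiment",
    "gen_cross_section", "gen_droplet_series", "gen_cohort", "Cohort",
    "eccentric_annulus_thickness",
]


class GroundTruth(BaseModel):
    """Known material/measurement parameters behind a synthetic dataset."""

    model_config = ConfigDict(extra="forbid", frozen=True,
                              allow_inf_nan=False)

    k0_true_Pa: float = Field(default=1000.0, gt=0,
                              description="reduced instantaneous stiffness")
    beta_true: float = Field(default=0.3, ge=0.0, le=1.0,
                             description="fluidity: 0 elastic, 1 viscous")
    alpha_true: float = Field(default=1.0, ge=1.0, le=2.0,
                              description="force-ramp shape exponent")
    eta_dorsal_Pa_s: float = Field(default=8e6, gt=0,
                                   description="dorsal Maxwell viscosity")
    eta_rest_Pa_s: float = Field(default=1.6e8, gt=0,
                                 description="non-dorsal Maxwell viscosity")
    E_shell_Pa: float = Field(default=1e4, gt=0,
                              description="shell elastic modulus")
    noise_sd: float = Field(default=0.0, ge=0,
                            description="additive Gaussian noise sd (signal units)")
    seed: int = Field(default=0, ge=0)

    def materials(self) -> MaterialParams:
        return MaterialParams(
            dorsal=Material(self.E_shell_Pa, self.eta_dorsal_Pa_s),
            rest=Material(self.E_shell_Pa, self.eta_rest_Pa_s),
        )


class CreepProtocol(BaseModel):
    """AFM loading protocol (defaults: the study's standard settings)."""

    model_config = ConfigDict(extra="forbid", frozen=True, allow_inf_nan=False)

    F_hold_nN: float = Field(default=AFM_PROTOCOL["F_hold_nN"], gt=0)
    ramp_time_s: float = Field(default=AFM_PROTOCOL["ramp_time_s"], gt=0)
    hold_time_s: float = Field(default=AFM_PROTOCOL["hold_time_s"], gt=0)
    bead_diameter_um: float = Field(default=AFM_PROTOCOL["bead_diameter_um"], gt=0)
    sample_rate_hz: float = Field(default=AFM_PROTOCOL["sample_rate_hz"], gt=0)


def gen_creep_experiment(gt: GroundTruth,
                         protocol: CreepProtocol | None = None) -> CreepRecord:
    """Synthetic AFM creep experiment.

    The force follows the piecewise ramp model with exponent
    ``gt.alpha_true`` (ramp onset at t = 0); the indentation is computed by
    the hereditary-integral oracle for the power-law material
    (k0_true, beta_true) and perturbed by additive Gaussian noise of sd
    ``gt.noise_sd`` (micrometres).
    """
    protocol = protocol or CreepProtocol()
    dt = 1.0 / protocol.sample_rate_hz
    n = int(round((protocol.ramp_time_s + protocol.hold_time_s) / dt)) + 1
    t = dt + np.arange(n) * dt  # start one sample after contact (t_C = 0)
    ramp = RampFit(F_C_nN=protocol.F_hold_nN, t_C_s=0.0,
                   dt_A_s=protocol.ramp_time_s, alpha=gt.alpha_true,
                   residual_rms_nN=0.0)
    force = afm_rheology.ramp_force(t, ramp.F_C_nN, ramp.t_C_s, ramp.dt_A_s,
                                    ramp.alpha)
    R_um = protocol.bead_diameter_um / 2.0
    indentation = hereditary_creep_oracle(ramp, gt.k0_true_Pa, gt.beta_true,
                                          T0_S, R_um, t)
    if gt.noise_sd > 0:
        rng = np.random.default_rng(gt.seed)
        indentation = indentation + rng.normal(0.0, gt.noise_sd, size=n)
    phase = np.where(t < protocol.ramp_time_s, "ramp", "hold").astype(object)
    return CreepRecord(time_s=t, force_nN=force, indentation_um=indentation,
                       bead_radius_um=R_um, phase=phase,
                       meta={"ground_truth": gt.model_dump()})


# ---------------------------------------------------------------------------
# cross-section contours

def _thickness_callable(kind: str, params: dict) -> Callable[[np.ndarray], np.ndarray]:
    if "thickness_fn" in params:
        return params["thickness_fn"]
    if kind == "annulus":
        h = float(params.get("thickness_um", 10.0))
        return lambda theta: np.full_like(np.asarray(theta, float), h)
    if kind == "dorsally_thinned":
        h_d = float(params.get("h_dorsal_um", 10.0))
        h_v = float(params.get("h_ventral_um", 40.0))
        # smooth dorsoventral gradient: thin at the roof (theta = 0), thick
        # at the floor (theta = pi)
        return lambda theta: h_d + (h_v - h_d) * (1.0 - np.cos(theta)) / 2.0
    raise ValueError(f"unknown cross-section kind {kind!r}")


def gen_cross_section(kind: str = "annulus", R_inner_um: float = 50.0,
                      n_points: int = 360, noise_sd: float = 0.0,
                      seed: int = 0, **params) -> CrossSectionContours:
    """Synthetic cross-section contours with point 0 at the dorsal midpoint.

    Kinds: ``annulus`` (constant thickness), ``eccentric`` (outer circle
    offset ventrally by ``offset_um``, radius ``R_outer_um``),
    ``dorsally_thinned`` (thin roof, thick floor), or any kind with an
    explicit ``thickness_fn(theta) -> um``.  Contours are counter-clockwise;
    angle 0 at 12 o'clock.
    """
    if n_points < 36:
        raise ValueError("n_points must be at least 36")
    if R_inner_um <= 0:
        raise ValueError("inner radius must be positive")
    theta = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    # angle 0 at the top, increasing counter-clockwise
    direction = np.column_stack([-np.sin(theta), np.cos(theta)])
    inner = R_inner_um * direction

    if kind == "eccentric":
        R_outer = float(params.get("R_outer_um", R_inner_um + 15.0))
        offset = float(params.get("offset_um", 5.0))
        if R_outer <= R_inner_um + offset:
            raise ValueError("outer circle must enclose the inner one")
        centre = np.array([0.0, -offset])  # shifted ventrally
        outer = centre + R_outer * direction
    else:
        h = np.asarray(_thickness_callable(kind, params)(theta), dtype=float)
        if np.any(h <= 0):
            raise ValueError("thickness_fn must be positive on [0, 2pi)")
        outer = (R_inner_um + h)[:, None] * direction

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inner = inner + rng.normal(0.0, noise_sd, inner.shape)
        outer = outer + rng.normal(0.0, noise_sd, outer.shape)

    return CrossSectionContours(inner=inner, outer=outer,
                                meta={"kind": kind, "R_inner_um": R_inner_um,
                                      **{k: v for k, v in params.items()
                                         if not callable(v)}})


def eccentric_annulus_thickness(theta, R_inner_um: float, R_outer_um: float,
                                offset_um: float) -> np.ndarray:
    """Closed-form radial thickness of an eccentric annulus.

    Distance from the inner-circle point at angle theta (0 at 12 o'clock,
    CCW; inner circle centred at the origin) along the outward radial ray to
    the outer circle of radius ``R_outer_um`` centred ventrally at
    (0, -offset).  Solves |p + t n - c| = R_outer for the positive root.
    """
    theta = np.asarray(theta, dtype=float)
    nx, ny = -np.sin(theta), np.cos(theta)
    px, py = R_inner_um * nx, R_inner_um * ny
    qx, qy = px - 0.0, py + offset_um
    q_n = qx * nx + qy * ny
    disc = q_n ** 2 - (qx ** 2 + qy ** 2) + R_outer_um ** 2
    return -q_n + np.sqrt(disc)


# ---------------------------------------------------------------------------
# droplet series

def gen_droplet_series(gt: GroundTruth, tube: TubeState, droplet: dict,
                       duration_h: float = 10.0, n_frames: int = 12) -> DropletSeries:
    """Droplet-rounding time series from the tube forward model, plus noise.

    ``droplet`` needs ``volume_nl`` and ``gamma_N_m``; the droplet must
    exceed the lumen-inscribed sphere so that it loads the wall.  Contour
    coordinates receive additive Gaussian noise of sd ``gt.noise_sd`` (um);
    the per-frame metrics are re-derived from the noisy contours.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t_grid = np.linspace(0.0, duration_h, n_frames)
    clean = tube_mechanics.droplet_in_tube_forward(tube, gt.materials(),
                                                   droplet, t_grid)
    if gt.noise_sd == 0:
        return clean
    rng = np.random.default_rng(gt.seed)
    noisy = [c + rng.normal(0.0, gt.noise_sd, c.shape) for c in clean.contours]
    series = DropletSeries.from_contours(clean.times_h, noisy,
                                         meta={"ground_truth": gt.model_dump()})
    return series


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class Cohort:
    """Paired per-embryo synthetic AFM records (hindbrain and spinal cord)."""

    hindbrain_records: list
    spinal_cord_records: list
    beta_hindbrain_true: np.ndarray
    beta_spinal_cord_true: np.ndarray
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.hindbrain_records)


def _truncated_betas(rng, mean: float, sd: float, n: int) -> np.ndarray:
    vals = rng.normal(mean, sd, size=n)
    bad = (vals < 0) | (vals > 1)
    n_resampled = 0
    while np.any(bad):
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        n_resampled += int(bad.sum())
        bad = (vals < 0) | (vals > 1)
    if n_resampled:
        warnings.warn(f"{n_resampled} fluidity draws outside [0, 1] resampled "
                      "with truncation")
    return vals


def gen_cohort(n_per_group: int, effects: dict | None = None, seed: int = 0,
               protocol: CreepProtocol | None = None,
               noise_sd: float = 0.05, generate_records: bool = True) -> Cohort:
    """Paired cohort with a group effect in fluidity.

    ``effects`` keys: ``beta_hindbrain_mean``, ``beta_spinalcord_mean``,
    ``sd`` (per-embryo between-subject scatter).  Defaults emulate the
    study's HH10-12 cohort: a more fluid dorsal hindbrain than spinal cord
    at n = 9 embryos, measured pairwise in the same embryo.  Per-embryo
    fluidity values are drawn from truncated normals on [0, 1]; with
    ``generate_records`` each value is turned into a full synthetic creep
    experiment for the fitting pipeline.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    effects = dict(effects or {})
    mean_hb = float(effects.get("beta_hindbrain_mean", 0.35))
    mean_sc = float(effects.get("beta_spinalcord_mean", 0.15))
    sd = float(effects.get("sd", 0.05))
    for name, m in (("beta_hindbrain_mean", mean_hb),
                    ("beta_spinalcord_mean", mean_sc)):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    beta_hb = _truncated_betas(rng, mean_hb, sd, n_per_group)
    beta_sc = _truncated_betas(rng, mean_sc, sd, n_per_group)

    rec_hb, rec_sc = [], []
    if generate_records:
        child_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * n_per_group)
        for i in range(n_per_group):
            gt_hb = GroundTruth(beta_true=float(beta_hb[i]), noise_sd=noise_sd,
                                seed=int(child_seeds[2 * i]))
            gt_sc = GroundTruth(beta_true=float(beta_sc[i]), noise_sd=noise_sd,
                                seed=int(child_seeds[2 * i + 1]))
            rec_hb.append(gen_creep_experiment(gt_hb, protocol))
            rec_sc.append(gen_creep_experiment(gt_sc, protocol))

    return Cohort(hindbrain_records=rec_hb, spinal_cord_records=rec_sc,
                  beta_hindbrain_true=beta_hb, beta_spinal_cord_true=beta_sc,
                  seed=seed,
                  meta={"effects": {"beta_hindbrain_mean": mean_hb,
                                    "beta_spinalcord_mean": mean_sc, "sd": sd}})
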