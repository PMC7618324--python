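"""End-to-end orchestration: synthesise -> fit -> simulate -> report.

A validated :class:`RunConfig` (unknown keys rejected) drives the stages in
dependency order; every output directory gets a provenance record with the
config hash, seed and library versions, so a rerun with the same config and
seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, afm_rheology, io, synthetic_data, tube_mechanics
from .defaults import DROPLET, ROOF_WINDOW_SHORT_UM, SINGLE_CELL_THICKNESS_UM
from .droplet_analysis import fit_rounding_timescale
from .synthetic_data import GroundTruth
from .tissue_shape import normalise_and_average, roof_metrics, thickness_profile
from .tube_mechanics import PressureSchedule, make_tube

log = logging.getLogger("neurotube.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_group: int = Field(default=9, ge=2)
    beta_hindbrain_mean: float = Field(default=0.35, ge=0.0, le=1.0)
    beta_spinalcord_mean: float = Field(default=0.15, ge=0.0, le=1.0)
    sd: float = Field(default=0.05, ge=0.0)
    noise_sd: float = Field(default=0.05, ge=0.0)


class TubeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    region: str = "hindbrain"
    schedule: str = Field(default="expansion",
                          pattern="^(expansion|intubation|bdx)$")
    duration_h: float = Field(default=20.0, gt=0)
    n_segments: int = Field(default=36, ge=4)


class DropletConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    region: str = "hindbrain_droplet"
    volume_nl: float = Field(default=DROPLET["hindbrain_volume_nl"], gt=0)
    gamma_N_m: float = Field(default=DROPLET["gamma_N_m"], ge=0)
    duration_h: float = Field(default=10.0, gt=0)
    n_frames: int = Field(default=12, ge=5)


class ShapeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sections: int = Field(default=3, ge=1)
    n_samples: int = Field(default=100, ge=10)
    single_cell_thickness_um: float = Field(default=SINGLE_CELL_THICKNESS_UM, gt=0)


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(default=0, ge=0)
    out_dir: str = "neurotube_run"
    stages: list[str] = Field(
        default_factory=lambda: ["synth", "fit_afm", "simulate_tube",
                                 "fit_droplet", "shape", "report"])
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    tube: TubeConfig = Field(default_factory=TubeConfig)
    droplet: DropletConfig = Field(default_factory=DropletConfig)
    shape: ShapeConfig = Field(default_factory=ShapeConfig)


def _provenance(config: RunConfig) -> dict:
    import scipy
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": config.seed,
        "neurotube_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the report.

    Any stage failure aborts with the failing stage named; outputs written
    before the failure are retained and listed as partial in the provenance
    record.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    report: dict = {"provenance": prov, "stages": {}}
    state: dict = {}

    stage_fns = {
        "synth": _stage_synth,
        "fit_afm": _stage_fit_afm,
        "simulate_tube": _stage_simulate_tube,
        "fit_droplet": _stage_fit_droplet,
        "shape": _stage_shape,
        "report": _stage_report,
    }
    order = [s for s in ("synth", "fit_afm", "simulate_tube", "fit_droplet",
                         "shape", "report") if s in config.stages]
    unknown = set(config.stages) - set(stage_fns)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    for name in order:
        log.info("stage %s: starting", name)
        try:
            result = stage_fns[name](config, out, state)
        except Exception as exc:
            prov["failed_stage"] = name
            io.write_json(report | {"partial": True}, out / "report.json")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = result
        log.info("stage %s: done (%s)", name,
                 ", ".join(result.get("outputs", [])))

    io.write_json(report, out / "report.json")
    return report


# ---------------------------------------------------------------------------
# stages

def _stage_synth(config: RunConfig, out: Path, state: dict) -> dict:
    c = config.cohort
    cohort = synthetic_data.gen_cohort(
        c.n_per_group,
        effects={"beta_hindbrain_mean": c.beta_hindbrain_mean,
                 "beta_spinalcord_mean": c.beta_spinalcord_mean, "sd": c.sd},
        seed=config.seed, noise_sd=c.noise_sd)
    state["cohort"] = cohort
    outputs = []
    for i, (hb, sc) in enumerate(zip(cohort.hindbrain_records,
                                     cohort.spinal_cord_records)):
        for region, rec in (("hindbrain", hb), ("spinal_cord", sc)):
            path = out / f"creep_embryo{i:02d}_{region}.csv"
            io.write_creep_csv(rec, path)
            outputs.append(path.name)
    io.write_json({"beta_hindbrain_true": cohort.beta_hindbrain_true,
                   "beta_spinal_cord_true": cohort.beta_spinal_cord_true,
                   "seed": config.seed},
                  out / "cohort_ground_truth.json")
    outputs.append("cohort_ground_truth.json")
    return {"n_per_group": cohort.n, "outputs": outputs}


def _stage_fit_afm(config: RunConfig, out: Path, state: dict) -> dict:
    if "cohort" not in state:
        raise RuntimeError("fit_afm requires the synth stage")
    cohort = state["cohort"]
    fits = {"hindbrain": [], "spinal_cord": []}
    rows = []
    for region, records in (("hindbrain", cohort.hindbrain_records),
                            ("spinal_cord", cohort.spinal_cord_records)):
        for i, rec in enumerate(records):
            ramp = afm_rheology.fit_force_ramp(rec)
            rheo = afm_rheology.fit_creep_powerlaw(rec, ramp)
            hertz = afm_rheology.fit_hertz_instantaneous(rec)
            fits[region].append(rheo)
            rows.append({"embryo": i, "region": region,
                         **afm_rheology.fit_to_dict(ramp, rheo, hertz)})
    pd.DataFrame(rows).to_csv(out / "afm_fits.csv", index=False)
    comparison = afm_rheology.paired_group_compare(
        fits["hindbrain"], fits["spinal_cord"], paired=True)
    stats = {
        "beta_hindbrain_mean": float(np.mean([f.beta for f in fits["hindbrain"]])),
        "beta_spinalcord_mean": float(np.mean([f.beta for f in fits["spinal_cord"]])),
        "paired_t": comparison.statistic, "p_value": comparison.p_value,
        "shapiro_p_hindbrain": comparison.shapiro_p_a,
        "shapiro_p_spinalcord": comparison.shapiro_p_b,
        "significant_at_0.05": comparison.significant,
    }
    io.write_json(stats, out / "afm_group_stats.json")
    state["afm_fits"] = fits
    return {**stats, "outputs": ["afm_fits.csv", "afm_group_stats.json"]}


def _stage_simulate_tube(config: RunConfig, out: Path, state: dict) -> dict:
    c = config.tube
    gt = GroundTruth()
    schedule = {"expansion": PressureSchedule.expansion,
                "intubation": PressureSchedule.intubation,
                "bdx": PressureSchedule.bdx}[c.schedule](c.duration_h)
    tube = make_tube(c.region, n_segments=c.n_segments)
    traj = tube_mechanics.simulate_tube(tube, gt.materials(), schedule,
                                        c.duration_h)
    traj.to_long_frame().to_csv(out / "tube_trajectory.csv", index=False)
    derived = traj.derived
    derived.to_csv(out / "tube_derived.csv", index=False)
    state["trajectory"] = traj
    last = derived.iloc[-1]
    return {"dorsal_thinning_ratio": float(last["dorsal_thinning_ratio"]),
            "rest_thinning_ratio": float(last["rest_thinning_ratio"]),
            "truncated": traj.truncated,
            "outputs": ["tube_trajectory.csv", "tube_derived.csv"]}


def _stage_fit_droplet(config: RunConfig, out: Path, state: dict) -> dict:
    c = config.droplet
    gt = GroundTruth(seed=config.seed, noise_sd=0.2)
    tube = make_tube(c.region)
    droplet = {"volume_nl": c.volume_nl, "gamma_N_m": c.gamma_N_m}
    series = synthetic_data.gen_droplet_series(gt, tube, droplet,
                                               c.duration_h, c.n_frames)
    io.write_droplet_csv(series, out / "droplet_contours.csv")
    rounding = fit_rounding_timescale(series)
    est = tube_mechanics.estimate_viscosity_from_droplet(
        series, tube, gt.materials(), droplet, seed=config.seed)
    result = {"tau_h": rounding["tau_h"],
              "eta_hat_Pa_s": est["eta_hat_Pa_s"],
              "eta_true_dorsal_Pa_s": gt.eta_dorsal_Pa_s,
              "ci_Pa_s": list(est["ci"]), "identifiable": est["identifiable"]}
    io.write_json(result, out / "droplet_fit.json")
    return {**result, "outputs": ["droplet_contours.csv", "droplet_fit.json"]}


def _stage_shape(config: RunConfig, out: Path, state: dict) -> dict:
    c = config.shape
    profiles = []
    for i in range(c.n_sections):
        section = synthetic_data.gen_cross_section(
            "dorsally_thinned", R_inner_um=50.0, h_dorsal_um=8.0,
            h_ventral_um=40.0, n_points=180, noise_sd=0.05,
            seed=config.seed + i)
        io.write_contours_csv(section, out / f"section_{i:02d}.csv")
        profiles.append(thickness_profile(section, n_samples=c.n_samples))
    avg = normalise_and_average(profiles)
    metrics = [roof_metrics(p, ROOF_WINDOW_SHORT_UM,
                            c.single_cell_thickness_um) for p in profiles]
    rows = pd.concat([p.to_frame().assign(section=i)
                      for i, p in enumerate(profiles)])
    rows.to_csv(out / "thickness_profiles.csv", index=False)
    result = {
        "poly_coeffs": avg["poly_coeffs"],
        "mean_roof_thickness_um": float(np.mean(
            [m["mean_roof_thickness_um"] for m in metrics])),
        "mean_roof_length_um": float(np.mean(
            [m["roof_length_um"] for m in metrics])),
        "roof_window_um": ROOF_WINDOW_SHORT_UM,
    }
    io.write_json(result, out / "shape_metrics.json")
    return {**{k: v for k, v in result.items() if k != "poly_coeffs"},
            "outputs": ["thickness_profiles.csv", "shape_metrics.json"]}


def _stage_report(config: RunConfig, out: Path, state: dict) -> dict:
    # the per-stage JSON artifacts are the report; this stage just inventories
    produced = sorted(p.name for p in out.iterdir() if p.is_file())
    return {"outputs": produced}
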