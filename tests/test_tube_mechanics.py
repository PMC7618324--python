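"""Maxwell pressurized-tube model: closed forms, conservation, presets,
droplet forward model and viscosity inversion."""

import numpy as np
import pytest

from neurotube.synthetic_data import GroundTruth
from neurotube.tube_mechanics import (Material, MaterialParams,
                                      PressureSchedule, droplet_in_tube_forward,
                                      estimate_viscosity_from_droplet,
                                      hoop_stress, make_tube, maxwell_step,
                                      simulate_tube)

RIGID = MaterialParams(Material(np.inf, np.inf), Material(np.inf, np.inf))
VISCOUS = MaterialParams(Material(1e12, 1e7), Material(1e12, 1e7))
ELASTIC = MaterialParams(Material(1e4, np.inf), Material(1e4, np.inf))


def constant_schedule(P, T=100.0):
    return PressureSchedule(np.array([0.0, T]), np.array([P, P]))


class TestHoopStress:
    def test_direct_formula(self):
        assert hoop_stress(25.0, 100.0, 10.0) == pytest.approx(250.0)

    def test_zero_pressure(self):
        assert hoop_stress(0.0, 100.0, 10.0) == 0.0

    def test_linear_in_radius(self):
        assert hoop_stress(15.0, 200.0, 10.0) == 2 * hoop_stress(15.0, 100.0, 10.0)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            hoop_stress(15.0, 100.0, 0.0)


class TestMaxwellStep:
    def test_zero_pressure_leaves_state_unchanged(self):
        tube = make_tube("hindbrain")
        out = maxwell_step(tube, VISCOUS, 0.0, 10.0)
        assert np.allclose(out.thickness_um, tube.thickness_um)
        assert np.allclose(out.arc_length_um, tube.arc_length_um)

    def test_elastic_limit_strain(self):
        # eta = inf: after the transient, strain is the elastic equilibrium
        tube = make_tube("hindbrain")
        traj = simulate_tube(tube, ELASTIC, constant_schedule(15.0), 5.0,
                             n_out=11)
        st = traj.states[-1]
        eps_expected = 15.0 * st.lumen_radius_um / (st.thickness_um[0] * 1e4)
        assert st.strain[0] == pytest.approx(eps_expected, rel=0.02)
        # no further flow once equilibrated
        assert traj.states[-1].strain[0] == pytest.approx(
            traj.states[-2].strain[0], rel=1e-6)

    def test_conservation_exact_per_step(self):
        tube = make_tube("hindbrain")
        out = maxwell_step(tube, VISCOUS, 20.0, 100.0)
        assert np.allclose(out.arc_length_um * out.thickness_um,
                           tube.arc_length_um * tube.thickness_um, rtol=1e-12)


class TestSimulateTube:
    def test_viscous_closed_form(self):
        # uniform purely viscous tube: R(t) = R0 [1 - 2 P R0 t/(eta h0)]^{-1/2}
        tube = make_tube("hindbrain")
        P, eta, h0 = 20.0, 1e7, 40.0
        R0 = tube.lumen_radius_um
        t_double = 0.75 * eta * h0 / (2 * P * R0) / 3600.0  # R reaches 2 R0
        traj = simulate_tube(tube, VISCOUS, constant_schedule(P), t_double,
                             n_out=41)
        d = traj.derived
        t_s = d["time_h"].to_numpy() * 3600.0
        R_exact = R0 / np.sqrt(1.0 - 2 * P * R0 * t_s / (eta * h0))
        rel = np.abs(d["lumen_radius_um"].to_numpy() - R_exact) / R_exact
        assert rel.max() < 0.005

    def test_conservation_over_trajectory(self):
        tube = make_tube("hindbrain")
        gt = GroundTruth()
        traj = simulate_tube(tube, gt.materials(),
                             PressureSchedule.expansion(20.0), 20.0)
        lh0 = traj.states[0].arc_length_um * traj.states[0].thickness_um
        lhT = traj.states[-1].arc_length_um * traj.states[-1].thickness_um
        assert np.max(np.abs(lhT / lh0 - 1.0)) < 1e-3

    def test_zero_schedule_keeps_thickness(self):
        tube = make_tube("hindbrain")
        traj = simulate_tube(tube, GroundTruth().materials(),
                             PressureSchedule.intubation(20.0), 20.0, n_out=11)
        assert np.allclose(traj.states[-1].thickness_um, tube.thickness_um)

    def test_dorsal_thins_more_than_rest(self):
        gt = GroundTruth()
        traj = simulate_tube(make_tube("hindbrain"), gt.materials(),
                             PressureSchedule.expansion(20.0), 20.0)
        last = traj.derived.iloc[-1]
        assert last["dorsal_thinning_ratio"] < last["rest_thinning_ratio"]
        assert last["dorsal_thinning_ratio"] < 0.8

    def test_spinal_cord_thins_less_at_every_time(self):
        gt = GroundTruth()
        sched = PressureSchedule.expansion(20.0)
        hb = simulate_tube(make_tube("hindbrain"), gt.materials(), sched, 20.0)
        sc = simulate_tube(make_tube("spinal_cord"), gt.materials(), sched, 20.0)
        r_hb = hb.derived["dorsal_thinning_ratio"].to_numpy()[1:]
        r_sc = sc.derived["dorsal_thinning_ratio"].to_numpy()[1:]
        assert np.all(r_hb < r_sc)

    def test_step_size_independence(self):
        gt = GroundTruth()
        sched = PressureSchedule.expansion(20.0)
        a = simulate_tube(make_tube("hindbrain"), gt.materials(), sched, 20.0,
                          d_eps_target=1e-3)
        b = simulate_tube(make_tube("hindbrain"), gt.materials(), sched, 20.0,
                          d_eps_target=5e-4)
        ra = a.derived["dorsal_thinning_ratio"].to_numpy()
        rb = b.derived["dorsal_thinning_ratio"].to_numpy()
        assert np.max(np.abs(ra - rb)) < 0.002

    def test_blowup_truncates_with_flag(self):
        tube = make_tube("hindbrain")
        fast = MaterialParams(Material(1e12, 1e5), Material(1e12, 1e5))
        with pytest.warns(UserWarning, match="truncated"):
            traj = simulate_tube(tube, fast, constant_schedule(25.0), 20.0)
        assert traj.truncated


class TestDropletForward:
    DROPLET = {"volume_nl": 4.0, "gamma_N_m": 0.01}

    def test_rigid_wall_keeps_aspect_ratio(self):
        tube = make_tube("hindbrain_droplet", n_segments=12)
        s = droplet_in_tube_forward(tube, RIGID, self.DROPLET,
                                    np.linspace(0, 10, 6))
        assert np.allclose(s.aspect_ratio, s.aspect_ratio[0])
        assert s.aspect_ratio[0] > 1

    def test_zero_surface_tension_freezes_shape(self):
        tube = make_tube("hindbrain_droplet", n_segments=12)
        s = droplet_in_tube_forward(tube, GroundTruth().materials(),
                                    {"volume_nl": 4.0, "gamma_N_m": 0.0},
                                    np.linspace(0, 10, 6))
        assert np.allclose(s.aspect_ratio, s.aspect_ratio[0])

    def test_aspect_ratio_decays_monotonically_to_one(self):
        tube = make_tube("hindbrain_droplet", n_segments=12)
        s = droplet_in_tube_forward(tube, GroundTruth().materials(),
                                    self.DROPLET, np.linspace(0, 20, 15))
        assert np.all(np.diff(s.aspect_ratio) <= 1e-12)
        assert np.all(s.aspect_ratio >= 1.0 - 1e-12)
        assert s.aspect_ratio[-1] == pytest.approx(1.0, abs=1e-6)

    def test_small_droplet_rejected(self):
        tube = make_tube("hindbrain_droplet", n_segments=12)
        with pytest.raises(ValueError, match="lumen sphere"):
            droplet_in_tube_forward(tube, GroundTruth().materials(),
                                    {"volume_nl": 0.3, "gamma_N_m": 0.01},
                                    np.linspace(0, 10, 6))

    def test_relaxation_time_scales_with_viscosity(self):
        from neurotube.droplet_analysis import fit_rounding_timescale
        tube = make_tube("hindbrain_droplet", n_segments=12)
        taus = []
        for factor in (1.0, 10.0):
            mat = GroundTruth().materials().scaled_eta(factor)
            s = droplet_in_tube_forward(tube, mat, self.DROPLET,
                                        np.linspace(0, 40 * factor, 15))
            taus.append(fit_rounding_timescale(s)["tau_h"])
        assert taus[1] / taus[0] == pytest.approx(10.0, rel=0.25)


class TestViscosityEstimate:
    DROPLET = {"volume_nl": 4.0, "gamma_N_m": 0.01}

    def test_noiseless_round_trip_within_10pct(self):
        gt = GroundTruth()
        tube = make_tube("hindbrain_droplet", n_segments=12)
        s = droplet_in_tube_forward(tube, gt.materials(), self.DROPLET,
                                    np.linspace(0, 10, 12))
        est = estimate_viscosity_from_droplet(s, tube, gt.materials(),
                                              self.DROPLET, n_boot=10, seed=0)
        assert est["identifiable"]
        assert est["eta_hat_Pa_s"] == pytest.approx(gt.eta_dorsal_Pa_s, rel=0.1)

    def test_flat_series_unidentifiable(self):
        tube = make_tube("hindbrain_droplet", n_segments=12)
        s = droplet_in_tube_forward(tube, GroundTruth().materials(),
                                    {"volume_nl": 4.0, "gamma_N_m": 0.0},
                                    np.linspace(0, 10, 8))
        est = estimate_viscosity_from_droplet(s, tube, GroundTruth().materials(),
                                              self.DROPLET, seed=0)
        assert not est["identifiable"]
        assert "eta_lower_bound_Pa_s" in est
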