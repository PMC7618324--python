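"""AFM creep rheology: ramp fitting, creep model vs hereditary oracle,
power-law parameter recovery, Hertz fit and group statistics."""

import math

import numpy as np
import pytest

from neurotube import afm_rheology as afm
from neurotube.afm_rheology import (CreepRecord, RampFit, creep_model_indentation,
                                    fit_creep_powerlaw, fit_force_ramp,
                                    fit_hertz_instantaneous,
                                    hereditary_creep_oracle,
                                    paired_group_compare, ramp_force)
from neurotube.synthetic_data import GroundTruth, gen_creep_experiment

from conftest import BEAD_RADIUS_UM


def make_record(alpha=1.0, F_C=50.0, t_C=0.0, dt_A=0.5, hold=3.0, rate=200.0,
                k0=1000.0, beta=0.3, noise=0.0, seed=0):
    """Record built from the hereditary oracle (independent of the closed form)."""
    ramp = RampFit(F_C_nN=F_C, t_C_s=t_C, dt_A_s=dt_A, alpha=alpha,
                   residual_rms_nN=0.0)
    dt = 1.0 / rate
    t = t_C + dt + np.arange(int((dt_A + hold) / dt)) * dt
    force = ramp_force(t, F_C, t_C, dt_A, alpha)
    delta = hereditary_creep_oracle(ramp, k0, beta, 1.0, BEAD_RADIUS_UM, t)
    if noise:
        delta = delta + np.random.default_rng(seed).normal(0, noise, t.size)
    phase = np.where(t < t_C + dt_A, "ramp", "hold").astype(object)
    return CreepRecord(t, force, delta, BEAD_RADIUS_UM, phase)


# ---------------------------------------------------------------------------
# force-ramp fitting

class TestForceRamp:
    def test_linear_ramp_recovers_alpha_one(self):
        rec = make_record(alpha=1.0)
        fit = fit_force_ramp(rec)
        assert fit.converged
        assert fit.alpha == pytest.approx(1.0, abs=1e-3)
        assert fit.F_C_nN == pytest.approx(50.0, rel=1e-6)
        assert fit.dt_A_s == pytest.approx(0.5, rel=1e-4)

    def test_quadratic_ramp_hits_upper_bound(self):
        rec = make_record(alpha=2.0)
        fit = fit_force_ramp(rec)
        assert fit.alpha == pytest.approx(2.0, abs=1e-3)

    @pytest.mark.parametrize("alpha", [1.2, 1.5, 1.8])
    def test_round_trip_intermediate_alpha(self, alpha):
        gt = GroundTruth(alpha_true=alpha, noise_sd=0.0)
        fit = fit_force_ramp(gen_creep_experiment(gt))
        assert fit.alpha == pytest.approx(alpha, abs=0.01)

    def test_too_few_ramp_samples_refused(self):
        rec = make_record(rate=200.0)
        keep = np.concatenate([np.arange(5), np.arange(150, rec.time_s.size)])
        short = CreepRecord(rec.time_s[keep], rec.force_nN[keep],
                            rec.indentation_um[keep], rec.bead_radius_um,
                            rec.phase[keep])
        with pytest.raises(ValueError, match="ramp"):
            fit_force_ramp(short)


# ---------------------------------------------------------------------------
# creep model vs hereditary oracle

class TestCreepModel:
    def test_elastic_limit_is_time_independent(self, standard_ramp, hold_time_grid):
        delta = creep_model_indentation(standard_ramp, 1000.0, 0.0, 1.0,
                                        BEAD_RADIUS_UM, hold_time_grid)
        # Hertz value (3 F / (4 k0 sqrt(R)))^(2/3) in um
        expected = (3 * 50e-9 / (4 * 1000.0 * math.sqrt(44.65e-6))) ** (2 / 3) / 1e-6
        assert np.allclose(delta, expected, rtol=1e-9)

    def test_doubling_k0_scales_indentation(self, standard_ramp, hold_time_grid):
        d1 = creep_model_indentation(standard_ramp, 1000.0, 0.3, 1.0,
                                     BEAD_RADIUS_UM, hold_time_grid)
        d2 = creep_model_indentation(standard_ramp, 2000.0, 0.3, 1.0,
                                     BEAD_RADIUS_UM, hold_time_grid)
        assert np.allclose(d2 / d1, 2.0 ** (-2.0 / 3.0), rtol=1e-12)

    def test_matches_oracle_spot_value(self, standard_ramp):
        t = np.array([standard_ramp.dt_A_s + 3.0])
        closed = creep_model_indentation(standard_ramp, 1000.0, 0.3, 1.0,
                                         BEAD_RADIUS_UM, t)
        oracle = hereditary_creep_oracle(standard_ramp, 1000.0, 0.3, 1.0,
                                         BEAD_RADIUS_UM, t)
        assert closed[0] == pytest.approx(oracle[0], rel=1e-3)

    def test_domain_error_before_contact(self, standard_ramp):
        with pytest.raises(ValueError, match="t > t_C"):
            creep_model_indentation(standard_ramp, 1000.0, 0.3, 1.0,
                                    BEAD_RADIUS_UM, np.array([-0.1]))

    @pytest.mark.parametrize("alpha", [1.0, 1.5, 2.0])
    @pytest.mark.parametrize("beta", [0.0, 0.4, 0.8])
    def test_oracle_equivalence_grid(self, alpha, beta, hold_time_grid):
        ramp = RampFit(F_C_nN=50.0, t_C_s=0.0, dt_A_s=0.5, alpha=alpha,
                       residual_rms_nN=0.0)
        closed = creep_model_indentation(ramp, 1000.0, beta, 1.0,
                                         BEAD_RADIUS_UM, hold_time_grid)
        oracle = hereditary_creep_oracle(ramp, 1000.0, beta, 1.0,
                                         BEAD_RADIUS_UM, hold_time_grid)
        assert np.max(np.abs(closed - oracle) / oracle) < 0.01


class TestHereditaryOracle:
    def test_elastic_reproduces_hertz_everywhere(self, standard_ramp):
        t = np.linspace(0.05, 3.5, 40)
        delta = hereditary_creep_oracle(standard_ramp, 1000.0, 0.0, 1.0,
                                        BEAD_RADIUS_UM, t)
        F = ramp_force(t, 50.0, 0.0, 0.5, 1.0) * 1e-9
        expected = (3 * F / (4 * 1000.0 * math.sqrt(44.65e-6))) ** (2 / 3) / 1e-6
        assert np.allclose(delta, expected, rtol=1e-3)

    def test_grid_refinement_converged(self, standard_ramp, hold_time_grid):
        coarse = hereditary_creep_oracle(standard_ramp, 1000.0, 0.5, 1.0,
                                         BEAD_RADIUS_UM, hold_time_grid,
                                         n_panels=50)
        fine = hereditary_creep_oracle(standard_ramp, 1000.0, 0.5, 1.0,
                                       BEAD_RADIUS_UM, hold_time_grid,
                                       n_panels=2000)
        assert np.max(np.abs(coarse / fine - 1)) < 1e-3

    def test_viscous_limit_grows_affinely(self, standard_ramp):
        # beta = 1: late hold-phase delta^{3/2} ~ F_C (t - t_C - dt_A/2)/(k0 t0)
        t = np.linspace(20.0, 40.0, 10)
        delta = hereditary_creep_oracle(standard_ramp, 1000.0, 1.0, 1.0,
                                        BEAD_RADIUS_UM, t)
        d32 = (delta * 1e-6) ** 1.5
        pred = (3 * 50e-9 / (4 * math.sqrt(44.65e-6))) * (t - 0.25) / 1000.0
        assert np.allclose(d32, pred, rtol=1e-6)


# ---------------------------------------------------------------------------
# creep power-law fitting

class TestCreepFit:
    def test_elastic_record_gives_zero_beta(self):
        rec = make_record(beta=0.0)
        fit = fit_creep_powerlaw(rec, fit_force_ramp(rec))
        assert fit.beta == pytest.approx(0.0, abs=0.02)
        assert fit.beta_at_bound

    def test_viscous_record_gives_unit_beta(self):
        rec = make_record(beta=1.0)
        fit = fit_creep_powerlaw(rec, fit_force_ramp(rec))
        assert fit.beta == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("k0", [500.0, 1000.0, 2000.0])
    @pytest.mark.parametrize("beta", [0.1, 0.3, 0.5])
    def test_noiseless_grid_round_trip(self, k0, beta):
        rec = make_record(k0=k0, beta=beta)
        fit = fit_creep_powerlaw(rec, fit_force_ramp(rec))
        assert fit.converged
        assert fit.k0_Pa == pytest.approx(k0, rel=0.05)
        assert fit.beta == pytest.approx(beta, abs=0.05 * max(beta, 0.1))

    def test_fitted_beta_monotone_in_true_beta(self):
        fitted = []
        for beta in (0.1, 0.3, 0.5, 0.7):
            rec = make_record(beta=beta)
            fitted.append(fit_creep_powerlaw(rec, fit_force_ramp(rec)).beta)
        assert np.all(np.diff(fitted) > 0)

    def test_short_hold_refused(self):
        rec = make_record()
        keep = rec.time_s < 0.52  # barely past the ramp
        short = CreepRecord(rec.time_s[keep], rec.force_nN[keep],
                            rec.indentation_um[keep], rec.bead_radius_um,
                            rec.phase[keep])
        with pytest.raises(ValueError, match="hold"):
            fit_creep_powerlaw(short, fit_force_ramp(rec))


# ---------------------------------------------------------------------------
# Hertz fit

class TestHertzFit:
    def test_exact_hertz_curve_recovered(self):
        t = np.linspace(0.005, 0.5, 100)
        delta = 10.0 * t  # um, approach at 10 um/s
        K = 1000.0
        F = (4 / 3) * K * math.sqrt(44.65e-6) * (delta * 1e-6) ** 1.5 / 1e-9
        phase = np.full(t.size, "ramp", dtype=object)
        rec = CreepRecord(t, F, delta, BEAD_RADIUS_UM, phase)
        fit = fit_hertz_instantaneous(rec)
        assert fit.K_Pa == pytest.approx(K, rel=1e-6)

    def test_scaling_law(self):
        t = np.linspace(0.005, 0.5, 100)
        delta = 10.0 * t
        F = (4 / 3) * 1000.0 * math.sqrt(44.65e-6) * (delta * 1e-6) ** 1.5 / 1e-9
        phase = np.full(t.size, "ramp", dtype=object)
        K1 = fit_hertz_instantaneous(
            CreepRecord(t, F, delta, BEAD_RADIUS_UM, phase)).K_Pa
        K2 = fit_hertz_instantaneous(
            CreepRecord(t, 2 * F, 2 * delta, BEAD_RADIUS_UM, phase)).K_Pa
        assert K2 / K1 == pytest.approx(2 ** -0.5, rel=1e-9)

    def test_weak_creep_K_close_to_k0(self):
        # ramp duration ~ t0 so the power-law compliance is near 1/k0
        # throughout the approach
        rec = make_record(beta=0.1, dt_A=1.0)
        fit = fit_hertz_instantaneous(rec)
        assert fit.K_Pa == pytest.approx(1000.0, rel=0.15)


# ---------------------------------------------------------------------------
# group comparison

class TestGroupCompare:
    def test_matches_textbook_t_statistic(self):
        a = np.array([0.30, 0.35, 0.40, 0.32, 0.38, 0.36, 0.31, 0.33, 0.37])
        b = np.array([0.15, 0.18, 0.12, 0.20, 0.14, 0.16, 0.17, 0.13, 0.19])
        res = paired_group_compare(a, b, paired=True)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.p_value < 0.05

    def test_identical_groups_flagged_degenerate(self):
        a = [0.3] * 5
        res = paired_group_compare(a, a, paired=True)
        assert res.degenerate
        assert not res.significant

    def test_unpaired_test_order_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.3, 0.05, 9)
        b = rng.normal(0.2, 0.05, 9)
        p1 = paired_group_compare(a, b, paired=False).p_value
        p2 = paired_group_compare(a, rng.permutation(b), paired=False).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_small_group_skips_normality_with_warning(self):
        with pytest.warns(UserWarning, match="Shapiro"):
            res = paired_group_compare([0.1, 0.2], [0.3, 0.4], paired=True)
        assert math.isnan(res.shapiro_p_a)
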