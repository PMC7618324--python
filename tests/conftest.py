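import numpy as np
import pytest

from neurotube.afm_rheology import RampFit
from neurotube.synthetic_data import CreepProtocol, GroundTruth, gen_creep_experiment

#: bead radius of the study's 89.3 um diameter probe
BEAD_RADIUS_UM = 44.65


@pytest.fixture(scope="session")
def standard_ramp() -> RampFit:
    """Linear 50 nN ramp reaching the hold in 0.5 s (onset at 0)."""
    return RampFit(F_C_nN=50.0, t_C_s=0.0, dt_A_s=0.5, alpha=1.0,
                   residual_rms_nN=0.0)


@pytest.fixture(scope="session")
def noiseless_record():
    """Noiseless synthetic creep experiment at beta = 0.3."""
    gt = GroundTruth(k0_true_Pa=1000.0, beta_true=0.3, alpha_true=1.0,
                     noise_sd=0.0)
    return gen_creep_experiment(gt)


@pytest.fixture(scope="session")
def hold_time_grid(standard_ramp):
    """Hold-phase sample times for the standard protocol (3 s hold)."""
    start = standard_ramp.t_C_s + standard_ramp.dt_A_s
    return np.linspace(start + 0.01, start + 3.0, 50)
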