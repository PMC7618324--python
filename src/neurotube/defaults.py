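"""Shared default constants.

All experimentally anchored protocol numbers live in this one table so that
every module (generators, fitters, CLI) agrees on them.  Units are the lab
units used throughout the package interfaces: seconds, nanonewtons,
micrometres, pascals, hours.
"""

# AFM creep protocol
AFM_PROTOCOL = {
    "F_hold_nN": 50.0,          # standard hold force; 75 nN also used
    "F_hold_alt_nN": 75.0,
    "approach_speed_um_s": 10.0,
    "hold_time_s": 3.0,
    "ramp_time_s": 0.5,         # typical time to reach the hold force at 10 um/s
    "bead_diameter_um": 89.3,
    "spring_constant_N_m": 0.01,  # nominal cantilever spring constant
    "sample_rate_hz": 200.0,
}

#: reference time for the power-law creep compliance J(t) = (1/k0) (t/t0)^beta.
#: k0 is therefore the reduced stiffness at t = t0; any other choice rescales
#: k0 by t0**beta.
T0_S = 1.0

# Lumen pressure schedule anchors (Pa)
PRESSURE = {
    "onset_Pa": 15.0,       # early brain expansion
    "late_Pa": 25.0,        # after expansion has progressed
    "intubation_Pa": 0.0,   # open lumen, pressure equalised
    "bdx_factor": 1.3,      # osmotic pressure increase of ~30%
}

# Tube geometry presets (thin-shell circular-lumen approximation).
# R0 = lumen radius, h0 = wall thickness, dorsal sector centred on the roof.
GEOMETRY_PRESETS = {
    "hindbrain": {"R0_um": 100.0, "h0_um": 40.0},
    "spinal_cord": {"R0_um": 30.0, "h0_um": 40.0},
    # pre-expansion hindbrain scale used for droplet experiments, where the
    # injected droplet must exceed the lumen-inscribed sphere
    "hindbrain_droplet": {"R0_um": 50.0, "h0_um": 40.0},
}
DORSAL_SECTOR_DEG = 60.0

# Ferrofluid droplet presets
DROPLET = {
    "hindbrain_volume_nl": 4.0,   # larger hindbrain lumen
    "spinal_cord_volume_nl": 1.0,  # smaller spinal cord lumen
    "gamma_N_m": 0.01,            # ferrofluid/medium surface tension (config input)
}

# Tissue-shape quantification windows
ROOF_WINDOW_SHORT_UM = 100.0   # intubation comparisons
ROOF_WINDOW_LONG_UM = 300.0    # BDX comparisons
SINGLE_CELL_THICKNESS_UM = 10.0  # threshold defining the single-cell-thick roof

SIGNIFICANCE_ALPHA = 0.05
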