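# Methods

This note records the models, conventions and numerical choices behind
`neurotube`, and what the synthetic-data tests do and do not establish.

## Power-law creep rheology of AFM indentation

A spherical bead (diameter 89.3 µm) indents the dorsal tissue surface at
10 µm/s until a set force (50 or 75 nN) is reached; the force is then held
for 3 s.  The measured force history is fitted with the piecewise ramp
model `F(t) = F_C·s(t)^α`, `s = clip((t − t_C)/Δt_A, 0, 1)`, with the
ramp-shape exponent α bounded in [1, 2] inside the optimiser (α = 1 is a
linear ramp; post-hoc clipping would bias the boundary cases and is not
used).

The material is a power-law solid with creep compliance
`J(t) = (1/k₀)(t/t₀)^β`.  For monotonically non-decreasing loading the
Lee–Radok hereditary integral gives

    δ^{3/2}(t) = (3 / (4√R)) ∫₀ᵗ J(t − t′) (dF/dt′) dt′ .

Substituting the fitted ramp yields the closed form used by the fitter,

    δ^{3/2} = (3 F_C α / (4 k₀ √R)) · (t−t_C)^{α+β} / (Δt_A^α t₀^β)
              · B(Δt_A/(t−t_C); α, β+1),

with `B(x; a, b)` the non-regularised incomplete beta function (upper limit
saturating at 1 during the ramp).  The closed form was derived
independently and is verified against a composite Gauss–Legendre quadrature
of the hereditary integral (`hereditary_creep_oracle`, 800 panels by
default, quadrature error < 0.1% by grid refinement); the quadrature is the
contractual ground truth wherever the transcription of the closed form
could be doubted.  Agreement is better than 1% over (α, β) ∈ [1,2]×[0,0.8]
on the hold phase.

Key limits, used as worked examples: β = 0 collapses to the Hertz response
`δ = (3F_C/(4k₀√R))^{2/3}` (time-independent hold); β = 1 with a linear
ramp gives `δ^{3/2} ∝ F_C(t − t_C − Δt_A/2)/(k₀ t₀)` exactly in the hold
phase.

### Parameters and conventions

* `t₀ = 1 s` (reference time of the compliance).  No value is dictated by
  the protocol; `k₀` is therefore the reduced stiffness at 1 s, and any
  other choice rescales `k₀` by `t₀^β`.  Configurable per call.
* Fitting: bounded trust-region least squares (`scipy.optimize.
  least_squares`), multi-start over β ∈ {0.1, 0.4, 0.7}, lowest residual
  wins; `k₀` is initialised from the elastic limit at the median hold
  indentation.  β estimates landing at a bound are flagged.
* Hold-only fitting is the default; the post-contact ramp samples can be
  included (`fit_phase="all"`).
* The Hertz fit `F = (4/3)K√R δ^{3/2}` is linear in `K` and solved in
  closed form on the approach samples.  `K` approximates `k₀` only for
  weakly creeping tissue and ramps lasting about `t₀`; at β ≈ 0.1 and a 1 s
  ramp the two agree within ~15%.
* Units: lab units (s, nN, µm, Pa) at every interface; SI internally.

## Maxwell pressurized-tube model

The neural tube cross-section is a thin circular shell of wall thickness
`h(θ)` discretised into angular segments (36 by default; the dorsal
compartment is a 60° sector centred on the roof).  Equilibrium sets the
hoop stress from the Laplace law, `σ = P·R/h`, per segment.  Each segment
is a Maxwell element, `dε/dt = σ/η + (1/E)dσ/dt`; tissue incompressibility
is imposed exactly by conserving `l·h` per segment, and the lumen radius
follows from `ΣL = 2πR`.  The integration step applies the dashpot flow
`dε = dt·σ/η` at the current stress, then relaxes the spring to the new
quasi-static equilibrium by capped (5%) strain increments; failure of that
fixed point to converge indicates genuine elastic runaway (`2σ/E ≥ 1`) and
aborts loudly.  Adaptive time steps keep the viscous strain increment near
10⁻³ per step; steps that would exceed 10% strain or exhaust thickness are
rejected and halved (at most 20 times).  Strains are re-referenced
multiplicatively each step (hypoelastic convention).  Radius growth beyond
10× the initial value truncates the trajectory with a flag.

Verified closed forms: the elastic limit ε = PR/(hE) (first order in
strain); and the uniform purely-viscous tube, for which the model matches
`R(t) = R₀[1 − 2PR₀t/(ηh₀)]^{−1/2}` to better than 0.5% up to twofold
radius growth.  Halving the step tolerance changes trajectories by < 0.2%.

### Geometry, pressures and materials

* Geometry presets: hindbrain `R₀ = 100 µm`, spinal cord `R₀ = 30 µm`, both
  `h₀ = 40 µm` — plausible scales at the relevant stages, configurable, not
  measured values.  A `hindbrain_droplet` preset (`R₀ = 50 µm`) represents
  the smaller pre-expansion hindbrain lumen in which droplets are placed; at
  the expanded 100 µm radius a 4 nl droplet would already fit inside the
  lumen-inscribed sphere and exert no wall load.
* Pressure schedules: expansion ramps ~15 → ~25 Pa (measured onset and late
  lumen pressures) over 20 h; intubation is 0 Pa (open lumen); the
  osmotic-treatment schedule is 1.3× the expansion baseline.
* Default materials: `E = 10⁴ Pa` both compartments, `η_dorsal = 8×10⁶
  Pa·s`, `η_rest = 1.6×10⁸ Pa·s` (20-fold contrast).  These were chosen
  once so that (i) elastic strains stay small against the viscous flow that
  carries the biology, (ii) the 20 h expansion run roughly halves the
  dorsal hindbrain thickness while the rest of the wall loses only a few
  percent, and (iii) droplet rounding takes hours — the regimes the model
  is meant to occupy.  Only the *ordering* of the compartment behaviours is
  asserted in tests, not these absolute values.
* The "high dorsal curvature" of the real spinal cord enters only through
  its smaller radius; bending stiffness and non-circular cross-sections are
  not modelled.  No growth/proliferation term is included.

## Droplet mechanics

A ferrofluid droplet larger than the lumen-inscribed sphere sits as a
sphero-cylindrical capsule whose caps have the local lumen radius `r = R`.
Its spherical-cap Laplace pressure `ΔP = 2γ/r` loads the wall, which creeps
by the Maxwell model above; the droplet volume is conserved (audited to
0.5%), so as `R` grows the capsule shortens and the aspect ratio
`A = L/(2R)` decays toward 1, at which point the droplet detaches from the
wall and the shape freezes.  Because `σ = ΔP·R/h = 2γ/h`, the rounding rate
is linear in `1/η`: the relaxation timescale is a direct viscosity readout,
and it is hours for tissue-like η — orders of magnitude beyond the
sub-second surface-tension/oil-viscosity scale, which is what makes the
measurement informative about the tissue.

Analysis conventions: the cap arc for curvature fitting is the 25% of
contour length nearest the end extremum along the major principal axis,
fitted with an algebraic (Kåsa) circle fit (collinear caps return infinite
radius with a flag); aspect ratio is major-axis length over maximum
perpendicular width; rounding series are summarised by
`A(t) = A_∞ + (A₀ − A_∞)exp(−t/τ)`, with a lower-bound flag when the
observation window is shorter than τ.  Only one principal curvature is
observable in a single cross-section, so the spherical-cap `2γ/r` (not the
full two-curvature Laplace law) is used, assuming axisymmetry.  The
ferrofluid surface tension γ is a configuration input (0.01 N/m default).

Viscosity inversion fits a single scale factor on the wall viscosities by
least squares between observed and simulated aspect-ratio decay.  The
objective is evaluated on a coarse (17-point, ±2 decades) then refined
(25-point) log₁₀η grid of forward simulations; each fit — including every
residual-bootstrap replicate behind the 95% percentile confidence interval
— is then a grid search with parabolic refinement on the cached curves.
Flat series (no decay beyond noise) are declared unidentifiable and return
a lower bound instead of a point estimate.  Noiseless round trips recover η
within a few percent; 10% is the asserted tolerance.

## Tissue-shape quantification

Thickness is measured from equally spaced arc positions on the inner (lumen)
contour along the local outward normal to the nearest intersection with the
outer contour, separately on both sides of the dorsal midpoint.  The
ventral midpoint is taken as the point half the inner perimeter from the
dorsal midpoint, so `s` normalises to 0 (dorsal) … 1 (ventral) on each
side.  Samples whose normal misses the outer contour are dropped with a
warning; profiles losing more than 10% of samples are refused.  Averaging
across specimens resamples each profile to a common `s` grid and fits a
single 4th-degree polynomial to the pooled samples of all profiles (pooled,
not side-averaged-first).

Roof metrics: mean thickness over raw arc windows of 100 µm (pressure-
equalisation comparisons) or 300 µm (osmotic-treatment comparisons) from
the dorsal midpoint, averaged over sides; and the single-cell-thick roof
length, the contiguous arc (both sides summed) at or below a 10 µm
threshold from the dorsal midpoint.  The threshold is a convention (the
anatomical criterion "single-cell thick" has no unique number) and is
configurable; the roof extends to the *last contiguous sample* at or below
threshold, with no sub-sample interpolation, so step-profile fixtures are
exact.  Apical intensity traces are max-normalised per specimen (mean
normalisation available) and binned into 2 or 3 equal-arc-length bins from
the dorsal-most position; bin means are trapezoidal integral means of the
piecewise-linear trace, so analytic fixtures are exact.

Group statistics are two-sided t-tests — paired for within-embryo
hindbrain/spinal-cord comparisons, independent otherwise — with per-group
Shapiro–Wilk normality checks (skipped with a warning below n = 3) and a
fixed 0.05 significance threshold reported, never silently decided.
Zero-variance comparisons are flagged degenerate rather than given a p.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their arguments and seed (identical seeds
give bit-identical output).  Noise is additive Gaussian — on indentation
for creep records, on contour coordinates for sections and droplets — the
simplest model of instrument jitter; magnitudes are free parameters, since
no measurement-noise levels are prescribed by the protocols.  Cohorts draw
per-embryo fluidities from truncated normals on [0, 1] (default means 0.35
hindbrain vs 0.15 spinal cord, sd 0.05, n = 9 paired), emulating the
study-sized paired design.

What passing tests show: the fitting pipelines recover known generating
parameters through their own forward models plus noise, the tube model
reproduces its closed-form limits and the qualitative selective-thinning
behaviour, and the statistics are calibrated under the null.  What they do
not show: correctness on real instruments (drift, contact-point error,
cantilever calibration), real segmentation noise (correlated, not i.i.d.
Gaussian), non-circular lumen geometry, axial mechanics, or growth — all
outside the model class generated here.

## Problem sizes

Defaults are sized for interactive use: 200 Hz creep sampling (3.5 s
records), 36 tube segments (12–24 in the droplet fits, where the load is
uniform per compartment), 12 droplet frames over 10 h, 100-seed
noise-recovery grids and 1000-cohort null calibration.  All are arguments.
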