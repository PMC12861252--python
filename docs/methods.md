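# Methods

This note records the model equations as implemented, the defaults shipped
with the package and why they were chosen, the numerical schemes, and the
limits of what the test suite demonstrates.

## Two-phase water activity (`thermo`)

Hyphal tissue is split into a solute phase (vacuole: mannitol, trehalose,
ions) and a biopolymer phase (cytoplasm + cell wall: protein, cell-wall
material).  Each follows multicomponent Flory–Huggins mixing; the common
water activity at a given total moisture is found from the equal-activity
condition, which is also the stationarity condition of the total mixing
free energy (the implementation cross-checks the two views in its tests).

*Composition defaults* (per kg dry matter): mannitol 0.12, trehalose 0.08,
ions 0.05, protein 0.20, cell-wall material 0.55.  These are representative
of shiitake dry matter, not measurements; every entry is configurable.  The
interaction parameters default to χ = 0.3/0.4/0 for the solutes and χ = 0.5
for both biopolymers.  χ = 0.5 (theta condition) is deliberate: it is the
largest value for which ln a_w is monotone in water content, so the
isotherm is guaranteed invertible and the partition residual has a single
root.  χ > 0.5 is fully supported — `partition_water` then scans for all
equal-activity roots and returns the free-energy minimizer — but it is not
a default, because a spinodal region inside the working isotherm is not
physical for an intact, well-mixed phase.

*Pressure coupling.*  The biopolymer phase's chemical potential carries the
cell-wall stress: ln a_w,2 = ln a_w,mix,2 + v_w·σ/(RT) with σ from the
Maxwell model (sign configurable through `elastic_sign`; the default makes
compression on drying lower the activity, which produces desorption-above-
adsorption hysteresis — the experimentally observed direction).

*Numerics.*  The solver-facing partition is a safeguarded Newton iteration
on the phase-1 water fraction with analytic derivatives, warm-started from
a spline of the relaxed-state split; a bisection fallback covers the rare
non-converged cell.  Tolerance on the activity equality is 1e-9.

## Viscoelasticity (`viscoelastic`)

Two Maxwell modes with internal reference polymer fractions φ_ref,i.  Base
modulus and relaxation time are log₁₀-linear in moisture (dry basis) with
an Arrhenius factor (Ea = 60 kJ/mol) on τ and floors to keep both
quantities finite:

| mode | log₁₀ G_base (Pa) | log₁₀ τ_base (s) |
|------|-------------------|------------------|
| slow | 8.0 − 0.5·X_m     | 7.5 − 5.0·X_m    |
| fast | 7.0 − 1.3·X_m     | 6.3 − 5.5·X_m    |

The steep τ slopes encode the central qualitative fact of the material:
relaxation takes minutes when wet and months-to-years when glassy-dry, so
drying locks stress into the wall.  The two modes carry *different*
moisture slopes; with equal slopes the two modal stiffness factors F_G0,
F_G1 would act only through one linear combination and could not be fitted
separately.  The τ floor is 10 s — effectively instantaneous on drying time
scales without injecting needless stiffness into the PDE integration.
Temperature dependence of G is neglected (the tissue glass transition sits
far below drying temperatures).  The internal-variable update for frozen
φ_s is the exact exponential, used directly by the explicit stepper; inside
the adaptive implicit drying integration the φ_ref,i ride along as ODE
states, which is equivalent in the resolved limit and lets the integrator
control the splitting error.

## Shrinkage and porosity (`structure`)

The gas/solid volume ratio follows the empirical two-branch law
(exponential 8.637·e^(−4.034 X) + 6.674 below X* = 0.95, linear
2.467·X + 4.33 above).  The printed branches do not meet at X* (jump
≈ 0.19); the module evaluates them as fitted by default and offers a linear
blend over X ∈ [0.90, 1.00], which the drying solver enables for
smoothness.  The law is applied per control volume at the local moisture.
ρ_solid defaults to 1500 kg/m³.  A consequence worth knowing: total tissue
volume shrinks with water loss only down to X ≈ 0.65 and then *grows*
again — the dry-end porosity rise associated with case hardening — so
volume is not monotone along a drying run.

## Transport properties (`transport`)

- Saturation pressure: Antoine correlation for water (1–100 °C), checked
  against an independent Magnus formula to 1 %.
- Vapor-in-air diffusivity: 2.5e-5 m²/s at 298 K, T^1.75 scaling.
- Effective conductivity: volume-weighted parallel mixture of
  λ_s = 0.2, λ_w = 0.6, λ_air = 0.026 W/m/K.
- Moisture diffusivity: Darken-type mutual diffusivity
  D = (φ_s D_w,self + φ_w D_s,self)·Γ with free-volume self-diffusivity
  D_self = d_dilute·(T/298.15)·10^(fv_slope·φ_s²), d_dilute = 3.0e-9 m²/s,
  fv_slope = −7.5, D_s,self/D_w,self = 0.3.  The quadratic exponent keeps
  the wet regime near the dilute limit while collapsing glassy-dry mobility
  by ~7 decades; the fitted F_w,diff multiplies the whole expression and
  absorbs level error by design.  The thermodynamic factor
  Γ = ∂ln a_w/∂ln φ_w is evaluated from the relaxed two-phase isotherm and
  floored at 0.5: the theta-solvent collapse of the osmotic modulus at high
  hydration is an artifact of treating cellular water as a continuum
  polymer solution.  These coefficients were set so that (i) the wet/dry
  diffusivity contrast exceeds 10³ and (ii) a standard 35 °C/30 % RH run
  shows a genuine constant-rate period whose center-temperature plateau
  matches the boundary-layer wet-bulb balance — the two qualitative
  signatures the correlation must reproduce.  They are defaults, not
  measurements.
- Exchange: h_rad = e·4σT_wall³ (σ = 5.70e-8 W·m⁻²·K⁻⁴ as used by the
  model), h_conv = 6 + 10·u_air, β_ext = F_w,conv·h_conv/(ρ_air c_p,air).
  β_ext is built from h_conv, not h_ext: radiation carries no mass.  The
  module also exposes the generalized wet-bulb temperature solving
  h_ext(T_air − T) = ΔH_evap·β_ext·(c_sat(T) − RH·c_sat(T_air)); with
  radiation off and F_w,conv = 1 this is the classical psychrometric
  balance.

## Drying solver (`solver`)

Lagrangian chain of control volumes of fixed solid mass: lamella cells
(dual porosity, hyphae fraction 0.5, exchanging with ambient through the
gap-scaled base area) at one end, hemispherical cap shells (equal solid
mass) up to the outer surface at the other; both chain ends exchange with
the air.  Geometry — volumes, radii, face areas, node positions — is
recomputed from the local moisture each evaluation through the shrinkage
law ("ideal shrinkage").  With the defaults (25 g fresh, X_m0 = 9,
ρ_solid = 1500) the initial cap radius comes out at 3.0 cm.

Conserved variables per cell: total moisture mass and enthalpy (reference
0 °C).  Temperature, liquid/vapor split and water activity are recovered
algebraically assuming local vapor equilibrium
c_v = a_w·M_v·p_sat(T)/(RT); vapor is always a sub-percent mass fraction,
so a short fixed-point (two passes, two inner temperature iterations) is
accurate and, importantly for the implicit integrator, smooth.  Fluxes are
assembled in conservative flux form — liquid diffusion
(−F_w,diff(1−φ_air)D∇c_w), pore vapor diffusion (−φ_air D_gas∇c_v),
conduction, upwinded sensible + latent advection — so interior totals
telescope exactly.  Boundary faces use β_ext(c_v,surf − c_air) and
h_ext(T_air − T) − ΔH_evap·β_ext(c_v,surf − c_air).  Two extra quadrature
states accumulate the boundary mass/energy flows, giving a global closure
check (typically ≤ 1e-7 relative for a full run).

Time integration: adaptive BDF (default rtol 1e-6) with a banded-ish
Jacobian sparsity pattern; the explicit `step` method (flux-form Euler plus
exact exponential Maxwell update) exists for conservation testing and
custom stepping.  The reported "center" is the cell farthest along the
chain from both exchange faces.

Defaults define a desk-scale study: 18 cap + 2 lamella cells, 15 % of the
solid in the lamella, T_init 25 °C.  The calibration profile (used by the
refit benchmarks) relaxes rtol to 1e-4, which changes drying curves by
≲ 1e-4 in y_w while halving run time.

## Calibration (`calibration`)

The objective sums, per experiment, mean squared residuals of
Θ = (T_p − T_init)/(T_air − T_init) and 10× the mean squared moisture
residual; simulated curves are linearly interpolated onto the sample times,
Θ uses the record's initial temperature and nominal air setpoint, and
center temperature is the temperature channel.  `sequential_search`
implements the sequential single-factor procedure: vary one parameter over
its candidate grid with the rest at the incumbent, accept the argmin,
cycle until a full pass brings no improvement.  Two pragmatic additions:
an exact-zero early exit (a numerically perfect fit cannot be improved)
and an optional pairwise-refinement stage — exhaustive two-factor sweeps
from the stalled point — because strictly one-at-a-time moves can stall on
ridges of the four-factor sorption objective.  Candidate grids:
e ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, F ∈ {0.1, 0.2, 0.5, 1, 2, 5, 8, 10}, and a
log grid {0.1, 0.3, 1, 3, 10, 30, 100} per sorption factor; neutral
starting points (e = 0.5, F = 1).

The DVS simulator integrates a lumped sample: dX_m/dt = k(RH − a_w) with
k = 3e-4 s⁻¹ (fixed from the first-step approach rate in experimental use),
dwell 6 h per RH step, 0.9→0.1→0.9 in 0.1 steps at 25 °C, coupled to the
Maxwell kinetics.  Integration is operator splitting on 48 fixed substeps:
exponential Euler for moisture (linearizing the isotherm locally, hence
stable no matter how steep it is) and the exact exponential for the
internal variables; halving the substep changes end-of-step moistures by
≈ 5e-6.  Desorption runs hold more water than adsorption runs at shared
humidities through two mechanisms: incomplete equilibration within a dwell
and locked-in wall stress.

## T₂ relaxometry and membrane state (`membrane_state`)

CPMG decays (TE = 0.5 ms, 12 000 echoes by default) are inverted on a
128-point log grid (0.1–10⁴ ms) by Tikhonov-regularized NNLS; the
regularization weight is chosen by the discrepancy principle against the
noise level (estimated from late-time echo differences when not given).
Water populations are local spectrum maxima at or above 5 % of the fresh
reference's global maximum; plateau maxima count once.  The state
classifier marks membrane integrity as lost when T_p > 40 °C or
y_w < 3 % (w.b.), with the boundary values themselves intact (strict
inequalities).  Conductivity maps are consumed as gridded CSV data and
interpolated bilinearly; they are never computed.

## Synthetic data (`synthetic_data`)

Generators produce everything the experimental record formats would
contain: solver output sampled at a logging interval with seeded Gaussian
noise, on/off or sinusoidal RH schedules mimicking dryer control (mean over
integer periods equals the base RH), and multi-exponential CPMG decays at
the instrument's acquisition parameters.  The four "HA" presets (33, 35,
38, 51 °C) share one absolute humidity — that of 30 % RH at 35 °C — as a
dryer drawing constant room air would; they are synthetic scenarios, not
measured logs.  What passing tests therefore show is internal consistency
of model, generators and fitting machinery under realistic conditions —
not agreement with any physical mushroom: sensor-contact bias, airflow
non-uniformity and geometric irregularity are all absent from the
generators.

## Self-consistency benchmarks (`benchmarks`)

The fitted parameters are validated by closed-loop recovery: synthesize
noise-free observations with the reported best-fit vector, refit from a
neutral start, require the exact generating values back (their objective
is identically zero, any other grid point is strictly positive).  The
drying benchmark uses 12 h at 35 °C and 7 h at 51 °C, sampled half-hourly
with 20 control volumes — long enough to cover the constant-rate period
and a substantial falling-rate stretch, which is where e/F_w,conv and
F_w,diff respectively leave their signatures.  The sorption benchmark uses
the full 17-step RH cycle.

## Known limitations

- No momentum balance: shrinkage is empirical, wrinkling/large deformation
  is out of scope.
- Solutes never cross the membrane; integrity loss is diagnosed, not fed
  back into the thermodynamics.
- One spatial dimension; the lamella-cap junction area is a geometric
  idealization.
- First-cycle sorption of freeze-dried samples (unknown stress history) is
  not addressed.
- Transport-correlation coefficients and tissue composition are
  literature-informed defaults, not fitted to measurements shipped with
  the package.
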