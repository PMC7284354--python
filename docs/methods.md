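# Methods

## Scope and model structure

`fbdry` models a six-cell segmented fluid-bed dryer as six identical
lumped cell models coupled through an air-routing layer and a discrete
scheduler. The modeling intent is a *soft sensor*: the model must run
much faster than real time from standard process measurements, and its
structure must stay simple enough for observer design. Accordingly the
drying physics is a single-rate phenomenological closure — no
falling-rate/diffusion kinetics, no particle-size effects, no bed
hydrodynamics, no cell-to-cell air maldistribution or inter-cell wall
heat transfer.

### Cell dynamics

States per cell: `m_g` (dry granules, kg), `m_w` (water in granules,
kg), `x_a` (cell-air water content, kg/kg dry air), `U_gw` (internal
energy of granules + water, J), `U_av` (internal energy of air + vapor,
J). The dry-air holdup `m_a` is a constant parameter (air-density
changes and granule-displaced volume neglected), which forces the
outlet dry-air flow to equal the net inlet flow at every instant.
Temperatures are reconstructed algebraically: `T_g = U_gw/(m_g c_g +
m_w c_w)` and `T_a` from inverting `U_av = m_a (c_p,a T_a + x_a (c_p,v
T_a + Δh_e))`. The reference state of all energies is dry air / liquid
water at 0 °C; all internal temperatures are in °C, only the ideal-gas
flow conversion uses Kelvin.

The evaporation rate `ṁ_w = k_m m_w (p_v,s − p_v) m̃̇_ai` uses the
vapor-pressure deficit of the **net inlet** air, not the cell air. A
consequence accepted by design is that cell air can exceed 100 % RH
under some conditions; relative humidity is therefore never clamped
anywhere in the package, and the mixed outlet humidity is only checked
and logged. The driving force is floored at zero: condensation is not
modeled, so supersaturated inlet air stops drying instead of wetting
the bed.

### Air routing

The AHU flow is split equally among the six cells regardless of fill
level. Pneumatic transport air (default 0 kg/s — its magnitude is a
config entry, `mdot_ap`) joins the filling cell and filter-blowback air
(20 m³/h for the first 10 s of the 30 s emptying phase, modeled as one
contiguous window; a pulse train changes nothing the balances can see)
joins the emptying cell, both at ambient condition, through an ideal
adiabatic mixing block. During emptying, `ṁ_ae = α_in,e ṁ_ai,t +
α_f,e ṁ_af` (α_in,e = 1/35, α_f,e = 0.13) leaves with the pneumatic
discharge. Its routing is not uniquely determined by its magnitude; it
is taken as an extra outlet stream at the well-mixed cell-air
condition, which leaves the cell ODEs untouched (every outlet carries
the same `x_a`, `T_a`) and conserves mass and energy exactly — only
the plenum flow seen by the outlet sensor becomes `m̃̇_ai − ṁ_ae`.

### Scheduler and hybrid integration

The fill rotation switches cells every 180 s; a cell dries for the
`tdry` value in force at the end of its fill window, empties for 30 s,
then idles. Emptying is realized as a discrete reset (`m_g = m_w = 0`,
`U_gw = 0`) at the phase edge, with the discarded water and energy
logged so global balances still close; cell air keeps evolving. The
continuous dynamics are integrated segment-wise between *all* discrete
events (fill switches, dry ends, empty/blowback edges, input setpoint
steps) with `scipy.integrate.solve_ivp`, restarting at each event so
discontinuities are never smeared. Five auxiliary cumulative states
(water in/out, enthalpy in/out, integrated wall loss) ride along in
the state vector, so balance closure is audited at integrator accuracy
rather than output-grid quadrature accuracy.

A configuration like `tdry > 5×180 s − 30 s` cannot fit the rotation;
the scheduler warns and lets the overlapping intervals stand (the
earlier phase wins), rather than failing.

## Parameters, units, defaults

| name | meaning | default | unit |
|---|---|---|---|
| `k1` | air-temperature blend weight in the transfer driving force | 0.381 | – |
| `kag` | air→granule heat-transfer coefficient | 3.22 | J/(K s) |
| `kloss` | wall heat-loss coefficient | 0.353 | J/(K s) |
| `km` | drying-rate coefficient | 1.77×10⁻⁵ | 1/kg (fitted scalar) |
| `ma` | dry-air holdup per cell | 0.197 | kg |
| `kV` | volume-flow correction factor | 0.807 | – |
| `ksep` | sensor air/granule blend weight | 0.1 | – |
| `cg` | specific heat of dry granules | 1300 | J/(kg K) |
| `tau_sensor` | PT100 first-order lag | 30 | s |

The defaults of the seven identifiable parameters are a nominal set
for a lactose/starch pre-blend on this dryer type; they serve as the
ground truth of the synthetic experiments and as the starting point of
identification. Dimensional analysis of the evaporation closure would
suggest 1/(Pa·kg) for `km`; it is carried as the fitted scalar it is,
with the nominal unit label 1/kg, and the ambiguity documented here
rather than resolved by rescaling.

Physical constants (`Rv` 461.5, `cp_a` 1005, `cp_v` 1860, `cw` 4186
J/(kg K), `Δh_e` 2.501×10⁶ J/kg) are standard moist-air values and are
deliberately user-overridable: identified transfer coefficients always
compensate for the constant set they were fitted with, so the constants
must be fixed and recorded before identification. `cg` = 1300 J/(kg K)
is a representative lactose/starch value and interacts with `kag`
during fitting — same reasoning. The granule inlet temperature `T_gi`
defaults to ambient (config entry).

The saturation-pressure correlation (quartic polynomial in the
exponent) is valid on 0–90 °C, agrees with standard psychrometric
references within 1 % at 0/20/45/60 °C, and is extrapolated with a
logged warning outside the window — transient optimizer iterates may
briefly leave it and a hard failure there would be worse.

## Sensors

Cell temperature sensing: convex blend `ksep T̃_ai + (1−ksep) T_g`
through a first-order lag, discretized exactly per output step
(`y[n] = a y[n−1] + (1−a) u[n−1]`, `a = exp(−Δt/τ)`), so the sensed
series is output-grid-robust. The filter state starts at ambient on a
cold start. The in-line LOD probe in cell 5 is an affine calibration
`LOD = 2.0218 raw − 1.571 %`; the synthetic generator inverts it to
produce raw readings, adds noise on the raw scale, and re-calibrates on
ingest — the model side works in true LOD throughout.

## Identification

The seven parameters are fitted by minimizing the largest of four
weighted sum-of-squares terms (outlet air temperature ×0.25, outlet
water content ×1000, six sensed cell temperatures ×1, masked cell-5
LOD ×2; weights inside the square). The evaluation window excludes
line heat-up, and the LOD term runs only over the probe's
drying-validity mask.

Numerics: all searching happens in a transformed space — log for
`km, kag, kloss, ma`, scaled logit for `k1, ksep ∈ (0,1)` and
`kV ∈ (0,2)` — enforcing bounds without constraints and making the
search unit-invariant. The minimization is two-stage:

1. trust-region least squares on the stacked weighted residual vector
   (finite-difference Jacobian). Its objective `ΣF_i` shares the
   minimizer with `max F_i` whenever the model can drive all terms
   toward zero, and Gauss–Newton curvature makes it far better
   conditioned than a direct simplex attack on the 7-parameter space;
2. adaptive Nelder–Mead on `max F_i` itself from the stage-1 point,
   which settles the genuinely nonsmooth Chebyshev optimum when the
   four terms cannot all vanish (the realistic, noisy case).

A failed candidate simulation returns a large-penalty sentinel rather
than raising, and the reported `F` vector is always re-evaluated at
the returned parameters (no stale caching). The identification solver
runs at relaxed tolerance (RK45, rtol 10⁻⁶, 5 s output grid) — at
these tolerances the non-stiff explicit pair is both faster and
sufficiently accurate (LOD agrees with an rtol 10⁻⁸ LSODA reference to
~10⁻⁷ %), and the optimizer performs several hundred simulations.

## Synthetic data: what passing tests do and do not show

The generator reproduces the stepwise setpoint schedules of the plant
identification and validation runs (feed fixed at 20 kg/h pre-blend +
40 g/min liquid; inlet air 40–50 °C; volume flow 260–400 m³/h; drying
time 480–680 s) and a reduced 45-minute three-step scenario for
desk-scale identification experiments. Unreported plant conditions are
declared synthetic defaults: ambient 20 °C / 40 % RH / 101325 Pa,
pre-blend LOD `wp` = 2 %, AHU inlet moisture equal to ambient moisture
(heating coil adds no water). Default measurement noise (0.2 °C
temperature, 5×10⁻⁵ kg/kg humidity, 0.15 % LOD) reflects plausible
instrument scales.

Because measured outputs are produced by the same model family that is
later fitted, parameter-recovery results demonstrate the correctness
and identifiability of the *pipeline* — not the fidelity of the model
to a physical dryer. Structural mismatch (sensor fouling, air
maldistribution, non-first-order drying) is exactly what the synthetic
route cannot probe.

## Numerical choices and degenerate inputs

- Default simulation: LSODA, rtol 10⁻⁸, atol 10⁻¹⁰, 1 s output grid.
  The problem sizes used in the shipped experiments (45-min reduced
  scenario at a 5 s grid for identification, the full 174-min schedule
  at 1 s for observer runs) were chosen as the smallest that exercise
  every manipulated input.
- Empty cell: granule temperature is undefined; the net-inlet air
  temperature is reported as a placeholder (so the sensor filter never
  sees NaN), the air–granule heat flow is gated to zero, and LOD is
  NaN-masked. The mass threshold for "empty" is 10⁻⁹ kg.
- Zero net inlet flow is a configuration error (raised), as is a zero
  total outlet flow in the mixing block; a supersaturated-beyond-
  pressure humidity request raises a domain error.
- Ties/edges: a grid sample exactly on a phase edge reports the
  post-transition (post-reset) state.

## Known limitations

- The trivial observer is open loop: any parameter or input bias
  propagates undamped into the LOD estimate. The natural next step, a
  corrective state observer using the measured cell temperatures, is
  out of scope here.
- Constant-rate drying only; very dry beds (falling-rate regime) will
  be predicted drier than reality.
- `ksep` enters both the model output and the target definition of the
  sensed-temperature objective term; the printed coupling is
  implemented as is, which makes `ksep` weakly identified when cell
  temperatures track the inlet temperature closely.
- In the reduced 45-minute scenario, `kloss` is weakly excited (wall
  loss is a few watts against kilowatt-scale enthalpy flows); its
  recovery is only tight because the noiseless fit is exact.
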