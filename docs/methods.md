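# Methods

This note records the model, the numerical choices, and the synthetic test
bed behind `voltrack`, together with the reasoning for decisions that were
genuinely open.

## Flow-map advection

**Model.** The backward flow map ψ(x, t) transports the current position x
to the position the same material point occupied at the start time t₀. Each
Cartesian component obeys the advective-form ("colour") transport equation
∂ψⁱ/∂t + u·∇ψⁱ = 0 with identity initial data. Volumes are represented as
level sets: a volume function f (f ≤ 0 inside, boundary counted as inside)
composed with ψ gives g(x,t) = f(ψ(x,t)) whose non-positive set is the
transported volume. Composition is a pure lookup; one ψ solve serves every
volume and shape.

**Why the non-conservative form.** Measured phase-contrast velocities are
not discretely divergence-free (noise, eddy currents, interpolation). The
conservative form would couple the divergence error into g and can violate
boundedness; the colour form keeps a discrete maximum principle regardless
of the divergence error, at the cost of exact discrete volume conservation
— which we then *measure* rather than assume (see the conservation test).

**Scheme.** Dimension-split finite volume on the acquisition grid:

* Godunov splitting with the sweep order alternated each sub-step
  (x→y→z, then z→y→x) so the leading splitting errors cancel pairwise;
* `upwind1` (default): donor-cell upwinding with *cell-centred* velocity
  signs. This is provably monotone for CFL ≤ 1 — the update is a convex
  combination of the three-point stencil — so each ψ component stays within
  its initial range. A face-averaged donor cell is only conditionally
  monotone in locally converging flow, which is why the cell-centred form
  is used for the monotone path;
* `high_resolution`: wave-propagation form with face-averaged velocities
  and MC-limited second-order corrections. Sharper interfaces, small
  over/undershoots possible; used for quantitative volume work;
* velocity linearly interpolated in time between frames and evaluated at
  each sub-step midpoint; sub-step count per interval is
  ceil(max_i |u_i|·Δt / (cfl·Δx_i)) with cfl target 0.9 (a CFL violation is
  never an error — the solver sub-steps);
* two zero-gradient ghost layers. Material entering the domain from outside
  the imaged volume inherits boundary ψ values; the solver flags this in
  `solver_meta["boundary_inflow"]`. Backward tracking runs the same solver
  on the time-reflected, negated field. With `cyclic_extension`, frames
  repeat with the cardiac period so tracking may cross the R-R boundary.

First-order upwind transports affine data exactly, so uniform translation
is reproduced to rounding error away from boundary influence; a quarter-turn
rigid rotation on a 32³ grid lands within 0.03 voxel of the analytic inverse
rotation with the high-resolution scheme (tested; the tolerance asserted is
0.5 voxel).

**Surfaces and volumes.** Iso-surfaces of g at level 0 are extracted by
marching cubes and oriented outward (toward g > 0) against the sampled
gradient. Volume is measured by voxel summation with a clamped linear
sub-cell occupancy, clip(1/2 − g/(|∇g| h), 0, 1) near the interface
(h = mean voxel pitch): this removes the O(h) staircase bias and is exactly
complementary under f → −f, so a function and its complement partition the
grid volume to rounding error.

## Preprocessing

**Background correction.** Eddy-current offsets are modelled per frame and
per component as v_bg = c0 + cx·x + cy·y + cz·z (x in mm, v in m/s) and fit
by OLS over a stationary-tissue mask (≥ 16 non-coplanar voxels; a
rank-deficient design raises). Fits are independent per frame because the
offsets drift over the cycle; `pool_time=True` fits one polynomial per
component across frames. Stationary tissue, when no mask is supplied, is
detected as voxels whose temporal mean and SD of speed both fall below a
threshold (default 0.03 m/s — about 3σ of typical velocity noise; note the
detection is biased against regions with large background offsets, which is
why parameter-recovery tests use a known mask and the pipeline treats
detection as a heuristic).

**Phase unwrapping.** Aliasing shifts measured values by multiples of
2·VENC. Correction is two-pass, per component: a temporal sweep from the
frame of minimum global speed (assumed wrap-free; at that point in the cycle
velocities are far from VENC) shifting each voxel by round(Δ/2VENC)·2VENC
against the previous corrected frame, then an iterated spatial pass shifting
voxels that differ from their 6-neighbour mean by more than VENC. Integer
rounding handles double wraps. The output is congruent to the input modulo
2·VENC at every value — the correction can relocate, never invent, velocity.
The assumed regularity is smoothness on the frame/voxel scale relative to
VENC; spatially or temporally white data at VENC amplitude would defeat any
unwrapping rule.

## Particle validation

The reference transport is deliberately independent of the flow-map solver:
classic fixed-step RK4 (default dt = frame interval / 10) on trilinear-in-
space, linear-in-time interpolated velocity — the interpolation model of the
visualization packages whose tracers are customarily trusted. Particles
leaving the imaged volume freeze at their last inside position and are
flagged, so the agreement denominator stays well-defined; they remain in the
denominator (the flag allows re-analysis excluding them).

The agreement statistic at a query time is the percentage of particles
released up to that time that are still on their release side of the tracked
surface (g ≤ 0 counts as inside, matching the volume definition; the release
side is the sign of f at the seed). If both methods transported material
identically the agreement would be exactly 100%; deviations measure the
combined discretization differences of the two methods, which is precisely
what the in-vivo validation of volume tracking measured against an external
tracer.

## Synthetic test bed

**Analytic kinds** (uniform, rigid rotation, shear, Lamb–Oseen vortex) have
closed-form transport used as oracles; the Lamb–Oseen oracle preserves the
radius and advances the angle by 1-D quadrature of the azimuthal rate, which
also covers the time-dependent (viscously spreading) core.

**Pulsatile vortex phantom.** Emulates diastolic LV inflow: a biphasic jet
through a "valve" plane that rolls up into a toroidal recirculation in a
chamber. The velocity is amp·a(t)·curl(A) with azimuthal potential
A_φ = r·exp(−r²/2R²)·sin²(π(z−z_lo)/(z_hi−z_lo)) about the long axis and a
waveform a(t) of two Gaussian bumps gated by a smoothstep valve opening.
The curl is taken with *central differences of the sampled potential*, so
the discrete (central-difference) divergence vanishes to rounding error —
exact incompressibility at the level the conservation tests probe.

Defaults are the study conditions: 96 mm cubic chamber on a 32³ grid (3 mm
voxels, matching the acquisition resolution the method targets), 25 frames
over a 1.0 s cycle (40 ms), VENC 1.0 m/s, E-wave peak 0.40 s at 0.6 m/s,
A-wave peak 0.90 s at half amplitude, valve opening at 0.30 s, valve plane
at 0.62 of the chamber height, jet core scale R = 0.18 of the chamber
height. The peak E velocity and biphasic timing are normal-physiology
values; the E-wave velocity–time integral that results (≈ 8 cm) is in the
normal transmitral range, so the tracked volumes undergo realistic, large
deformations. Amplitude is calibrated against the closed-form maximum speed
of the unit potential (grid-independent, so refining the grid refines the
same flow), and the generator reports ground-truth peak flows through the
valve disc from the closed-form flux 2πb²·s(b, z_valve) evaluated on the
frame grid.

**Measurement chain.** Corruption is applied in the fixed order truth →
+ first-order background → wrap at VENC → + Gaussian noise, i.e. offsets
alias together with the true signal and thermal noise rides on top, as in
phase-contrast acquisition. The generator returns the injected coefficients
and the wrapped-voxel mask so recovery is testable end to end.

**What the phantom does not model:** chamber walls as no-slip boundaries
(the potential tapers smoothly instead — masking would break
solenoidality), turbulence and beat-to-beat variability, partial-volume and
k-space acquisition effects, moving myocardium, and through-plane atrial
refill. Passing tests therefore demonstrate correct transport numerics
under realistic kinematics and noise, not fidelity to any particular
patient's hemodynamics.

## Validation experiments shipped with the package

* **Agreement experiment** (the synthetic analog of the in-vivo
  validation): 32³ phantom with noise SD 0.02·VENC; flow map from inflow
  onset with the high-resolution scheme; a transvalvular plane volume;
  1000 particles released every 20 ms during filling in a cylinder on the
  atrial side of the plane; agreement evaluated at mid-diastole (midpoint
  of the measured E/A peak times) and end-diastole (last frame). Typical
  results: 100% / ~99.9%. The particle-count sweep 1000–8000 changes the
  agreement by well under 0.2 percentage points (SD across counts).
* **Volume conservation**: a 17.3 mm-radius sphere (≈ 22 mL, the scale of
  an early-inflow bolus) centred on the long axis at 0.30 of the chamber
  height, tracked over the full cycle of the noise-free phantom. Measured
  drift ≈ 2.4% at 32³ and ≈ 0.7% at 64³. Smaller boluses (≈ 4 voxel radius)
  shear into sheets near the grid scale and drift more — a resolution
  limit, not a conservation defect, which is why the shipped experiment
  uses the physiologic bolus size.
* **Preprocessing recovery**: injected background recovered exactly
  (noise-free) and within OLS sampling error (noisy); ≥ 99% of wrapped
  voxels restored on a 1.4·VENC jet with 2% noise.

Problem sizes (32³/64³ grids, 25 frames, ≤ 8000 particles) were chosen so
the full suite and the acceptance script each run in minutes on one CPU
while still resolving the phantom's vortex by 5–10 cells across the core.

## Degenerate inputs and tie-breaks

g = 0 is inside, everywhere (volume definition, side classification,
occupancy). Out-of-grid queries are clamped to the boundary and flagged,
never extrapolated. Out-of-grid velocity samples are zero and flagged.
Empty level sets give empty meshes (not an error). A segment with no lumen
voxels is reported not-evaluable (NaN occupancy, absent). Two identical
constant rater tables give κ = 1 by convention, with a warning. The E/A
peak finder takes the two largest positive local maxima and raises an
ambiguity error listing candidates when fewer than two exist.

## Known limitations

* The finite-volume surface diffuses over long integrations; accuracy
  claims here are anchored to analytic oracles, not to any original
  implementation of flow-map advection, whose scheme details may differ in
  dissipation.
* Phase unwrapping assumes the minimum-speed frame is wrap-free and the
  field is smooth at the voxel/frame scale; pathological aliasing (wraps in
  every frame, or wrapped regions larger than their unwrapped
  neighbourhood) can defeat it.
* The segment model's angular origin and central-core extent (50% of local
  lumen radius) are declared conventions; occupancy is a voxel fraction,
  i.e. a deliberate quantification of what human observers judge visually.
* End-diastole is operationalized as the final frame of the gated cycle.
* NIfTI inputs are reoriented to the nearest canonical axes; oblique
  acquisitions are supported through the affine but velocities are assumed
  to be stored as physical world-axis components (scanner phase-to-velocity
  scaling is upstream of this package).
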