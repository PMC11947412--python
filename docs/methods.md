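# Methods

This note records the models behind `kneetwin`, the parameters that matter,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not demonstrate.

## Joint coordinate system

Knee motion is described in the Grood–Suntay joint coordinate system: a
femoral body-fixed flexion axis `e1`, a tibial body-fixed long axis `e3`,
and a floating axis `e2 = e3 × e1` (normalised).  At neutral both frames
coincide with x = medial→lateral (right knee), y = anterior,
z = distal→proximal; with that embedding the angular decomposition is an
intrinsic x–y′–z″ Euler sequence, which is what the implementation uses.
Signs follow clinical usage for a right knee (positive flexion bends the
knee, positive adduction is varus, positive internal rotation turns the
tibia inward); a `side="left"` flag flips adduction, internal rotation and
the ML translation and nothing else, so left-knee data can be processed
without re-deriving the mathematics.

Translations are the *contravariant* components of the tibial-origin vector
on the (e1, e2, e3) axis triad — "the translation along each axis" — which
makes the pose ↔ coordinates round trip exact (observed ≤ 3 × 10⁻¹⁴ over
1000 random poses; the test bound is 10⁻⁹).  The convention is singular
when `e1 ∥ e3`; decomposition raises an explicit gimbal error within 10⁻⁶
degrees of adduction ±90° rather than silently clamping.

### Loads in the JCS

Simulators report loads "at the origin of the tibial coordinate system".
Two readings exist and both are implemented:

* **projection** (default): each JCS load component is the dot product of
  the force/moment with the corresponding axis.  This is the conventional
  simulator reading.
* **conjugate**: the generalized loads strictly conjugate to the six JCS
  coordinates.  These differ from the projections only in the flexion and
  adduction moments, by a force term through ∂t/∂angle whenever the joint
  translation is nonzero (the floating and tibial axes rotate with the
  angles, carrying the origin with them).  The conjugate Jacobian is
  analytic; an independent central-finite-difference virtual-work check
  agrees to ~10⁻⁸ relative (bound 10⁻⁶, step 10⁻⁶, error measured against
  the work magnitude scale).

Sign convention for loads: compression is a *negative* IS force and a
positive AP force pushes the tibia anteriorly.  Published standardized
load-case tables print compressive axial loads as negative values (e.g.
mean compressions of −842 N to −1553 N), and the package follows the
printed numbers.

## Load-case transfer

**Scaling.**  Telemetric loads are normalised to a target body weight
(AVER75: 75 kg) by multiplying all force and moment channels by the
body-weight ratio.  Moments scale by the same ratio as forces because lever
arms do not change with the scaling; kinematic channels and the cycle
frequency are untouched.

**Re-registration.**  A `FrameRegistration` is a proper rigid transform; a
point with source-frame coordinates x has target coordinates `R·x + r`,
with `r` the source origin expressed in the target frame.  Wrenches
transform by the standard adjoint — force rotated, moment rotated plus the
transport term `r × F` — which preserves |F| and F·M; poses are conjugated
by the femoral and tibial registrations (equal by default, reflecting the
matched-functional-surfaces assumption).  The stock registration tilts by
6.5° about the ML axis (the posterior-slope correction between an
ultra-congruent donor design implanted at 8.5° slope and a
cruciate-retaining recipient at ~2°) and shifts the origin by 0.98 mm.

**Periodisation.**  Cyclic (iterative-learning) control needs matching
cycle endpoints.  The cycle is extended by 15 % of its duration
(`ceil(1.15·N)` samples; "duration" means the implied cyclic period
N·dt, which makes the measured extension exactly 15 % for N divisible
by 20).  The appended segment is a quintic Hermite blend matching value,
first derivative and a finite-difference second derivative at the old end
and at the cycle start — smooth, bounded, ring-free — and the final sample
is forced bitwise equal to the first.  The extension is appended (not
prepended or split); original samples are preserved bitwise, so analyses
restricted to the original cycle are unaffected.  Where the end state
differs from the start state any C¹ reconnection must leave the data's
envelope briefly; for channels that are already periodic with matching
slopes the blend stays within the channel's min/max range.

## Virtual ligament apparatus

Each of the 12 strands is a tension-only line element from a femoral
origin to a tibial insertion with the classic toe-region law

    f(ε) = 0                    ε < 0
         = ¼·k·ε²/ε₁            0 ≤ ε ≤ 2ε₁       (toe region)
         = k·(ε − ε₁)           ε > 2ε₁           (linear region)

with ε₁ = 0.03 and k in newtons per unit strain (a config reader accepts
N-per-percent tables and converts).  Both branches give k·ε₁ at ε = 2ε₁
with equal slope k, so f is C¹ and non-decreasing.

Strain comes from the reference length l_r (strand length at the reference
pose, usually full extension) and reference strain ε_r (pre-tension at that
pose).  The default model is the standard form ε = (l·(1+ε_r) − l_r)/l_r,
i.e. strain relative to the zero-load length l_r/(1+ε_r): a strand shorter
than its zero-load length is slack, which the force law's ε < 0 branch
requires.  A second model, ε = ε_r·l/l_r (a pure rescaling that reproduces
ε_r at the reference pose but never reaches zero for ε_r > 0 and therefore
has no slack regime), is retained behind `strain_model="as_printed"` for
fidelity comparisons with simulator firmware that may implement it; it is
not the default precisely because it contradicts the zero-force-below-zero-
strain rule.

Strand force acts on the tibia at the insertion point, directed at the
femoral origin; moments are taken about the tibial origin.  The reaction on
the femur is not tracked — the simulator sums ligament loads into the
tibial load channel only.  Point-to-point elements cannot wrap around bone;
no wrapping is modelled.

### Fixture apparatus

The strand table (4 capsular, 3 medial, 3 lateral, 2 PCL bundles) is a
synthetic fixture on a generic-size right knee — supplementary parameter
tables of physical setups are not reproduced.  Attachments were placed for
qualitative anatomical behaviour: the collaterals near-isometric and
pre-tensioned (ε_r = 0.04–0.05) so they carry load across the flexion
range; the posterior capsule taut only near extension; the PCL femoral
attachments within ~3 mm of the flexion axis inside the notch, which makes
the PCL slack near extension and progressively engaged above ~40° flexion —
the geometric mechanism behind its clinical role of restraining posterior
tibial translation in flexion.  Stiffnesses (1.2–9 kN per unit strain) are
literature-style magnitudes, not measurements.  A seed jitters attachment
coordinates by ±0.5 mm without changing topology or parameters.

## The quasi-static twin

The physical machine's per-DOF hybrid control and its iterative learning
controller (ILC) act on a plant with dynamics; the twin has none, so ILC
would be vacuous.  Instead each time step is solved directly: flexion and
internal-external rotation are clamped to the position targets, and the
four load-controlled coordinates (adduction, ML, AP, IS) are iterated until
contact-plus-ligament load matches the target on those channels.

* **Contact**: frictionless penalty contact between analytic surfaces —
  femoral condyles as spheres (radius 25 mm, centres ±22 mm on the ML
  axis), tibial compartments as concave spherical dishes (radius 30 mm,
  bottoms on the plateau) or planes.  Normal force k_c·δⁿ with
  k_c = 5000 N/mm and n = 1 by default; penetration δ from closed-form
  sphere–dish / sphere–plane geometry.  The ball-in-dish pairing gives the
  load-dependent lateral restoring stiffness (≈ N/(R_dish − R_sphere)) a
  conforming insert has.  Frictionlessness reflects lubricated testing.
* **Solver**: damped Newton with a numerical Jacobian (central differences,
  step 10⁻⁵ mm/deg), Levenberg-style λ adaptation, a 5 mm/deg trust region
  and at most 50 iterations; moment residuals are weighted ×10 so the
  mixed-unit norm balances the 0.5 N / 0.05 N·m machine tolerances.  Cold
  starts bracket and bisect the IS translation on the axial channel; within
  a run each step warm-starts from the previous.  The iteration refines to
  an inner tolerance of 10⁻⁷ N so that re-solving from a different warm
  start reproduces the pose far below 10⁻⁶, making the second cycle
  bitwise-stable in practice.  Residuals reported per step are recomputed
  from the returned pose, not taken from solver internals; non-convergence
  flags the step (a run with > 10 % flagged steps is marked failed) rather
  than raising, mirroring how physical runs are judged.
* **Cycles**: the machine's 300-cycle convergence protocol is
  re-interpreted as cycle-periodicity of the quasi-static solution.  Two
  cycles suffice — the system has no memory — and the reported
  cycle-to-cycle pose change is ~10⁻¹¹.
* **Compliance compensation**: the machine frame deforms under load without
  its sensors registering it, so strand referencing at the nominal pose
  would misstate ligament pre-tension.  Following the mean-compression
  recipe, the reference pose is the nominal pose shifted along the tibial
  long axis by compliance × (time-weighted mean axial load of the cycle);
  zero compliance reduces exactly to plain referencing.
* **Footprints**: the union over a pose trajectory of the analytic
  contact-patch circles (chord circle on planes, two-sphere intersection on
  dishes), rasterised on a tibial-surface grid (cell-centre test).  This is
  a qualitative analog of scanning-spray footprints, not a stress map; at
  0.1 mm resolution the static sphere-on-plane patch area is within 0.1 %
  of the chord-circle closed form.
* **Binned comparison**: samples are split into flexion/extension phases by
  the sign of the flexion rate and binned by flexion angle; soft-tissue
  variants are compared as per-bin mean deltas of AP translation, adduction
  and IS force.

## Synthetic load cases

Waveforms are sums of raised-cosine bumps on the unit cycle — smooth,
deterministic given a seed, and pinned to the printed landmarks: level
walking 0.625 Hz / 49° peak flexion / 2,401 N peak compression; squat
0.2 Hz / 2,336 N; stairs down 87° / 2,943 N; downhill walking 2,930 N.
Values without a printed source are fixture defaults chosen once for
plausibility: downhill 0.5 Hz / 62°, stairs down 0.45 Hz, sit-to-stand
0.25 Hz / 85° / 2,200 N, squat 80°, and all AP/ML force, abduction-moment
and axial-rotation channel magnitudes (set to small fractions of the
compressive peak with physiologically signed shapes — AP forces posteriorly
directed through mid-cycle and deep flexion, abduction moments biased
medially).  Locomotion ADLs share a stance/swing two-hump compression shape
and start/end near 0° flexion; sit-to-stand starts and ends at its flexion
maximum.  Flexion maxima and compression minima hit their landmark values
exactly by construction (channels are rescaled after the endpoint-mismatch
drift is injected).  The default 3 % endpoint mismatch makes raw tracks
non-periodic so periodisation is exercised.

Problem sizes used by the test suite and the acceptance script — 48–100
samples per cycle, two cycles per run — were chosen as the smallest grids
on which the waveform features and the flexion-binned analysis are well
resolved.

## What the synthetic test bed does and does not show

The generator emulates the *structure* of standardized instrumented-implant
data (channel set, control allocation, landmarks, endpoint mismatch), not
its waveform detail; the toy spherical surfaces reproduce conforming-implant
load sharing but not real insert topography; ligament parameters are
plausible, not identified.  Passing tests therefore demonstrate that the
transfer chain is exact, the mechanics are internally consistent (analytic
contact, superposition, symmetry, virtual work), and the soft-tissue
variations act in the clinically expected directions — PCL resection shifts
the AP equilibrium posteriorly above 40° flexion and much less below 30°;
stiffening one collateral group tips adduction toward that side.  Effect
*magnitudes* on the toy joint (a few tenths of a millimetre / degree) are
not comparable to measurements on physical implants, where reported AP
shifts reach millimetres.  On the question of the direction of the PCL
effect, the mechanically expected posterior shift under flexion is the
behaviour implemented and tested.  For the collateral-stiffening sign, the
toy geometry's outcome (stiffened side pulls the joint into its own-side
angulation) is documented as the twin's behaviour without claiming fidelity
to any physical rig.

## Known limitations

No friction, wear, creep, viscoelasticity or inertial dynamics; no post-cam
contact for posterior-stabilised designs; no ligament wrapping; no
frame-orientation optimisation for kinematic crosstalk removal.  The
registration transform is user-supplied configuration, not derived from
implant CAD.  Degenerate inputs are rejected with named errors (coincident
strand attachments, non-uniform time grids, gimbal proximity, dish radius
smaller than the condyle, zero condyle spacing).
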