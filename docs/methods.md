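# Methods

## The model

`btslip` simulates sagittal-plane bipedal walking of a *bipedal trunk
spring-loaded inverted pendulum* (BTSLIP): a rigid trunk (mass m = 80 kg,
inertia J = 4.6 kg m², hip point r_h = 0.1 m below the CoM on the trunk
axis) carried by two massless prismatic spring legs (rest length l0 = 1 m,
dimensionless stiffness k_N = 40, so k = k_N·m·g/l0 = 31 392 N/m).  Feet
lie on the ground (y = 0) and do not slip.  With generalized coordinates
(x, y, φ) — CoM position and trunk angle from the horizontal — each stance
leg transmits

    GRF_x = Fs (x_h − x_f)/l + τ y_h / l²,
    GRF_y = Fs y_h / l − τ (x_h − x_f)/l²,

where Fs = k (l0 − l) is the axial spring force (repulsive positive; the
printed convention k(l − l0) would push a compressed leg into the
ground and is corrected to the physically consistent sign), l the leg
length, and τ the hip torque exerted between the trunk and that stance
leg.  The trunk obeys m ẍ = ΣGRF_x, m ÿ = ΣGRF_y − m g and
J φ̈ = Στ + r_h(ΣGRF_x sin φ − ΣGRF_y cos φ).

Walking alternates single and double support.  Touchdown happens when the
swing foot — carried massless-ly at length l0 along the velocity-based
leg-adjustment (VBLA) direction O = (1−μ)V + μ(0,−g), μ = 0.34 — reaches
the ground; takeoff when a stance leg's vertical GRF crosses zero.  Losing
both contacts, dropping the hip below 0.2 m, or pitching the trunk more
than 60° from vertical counts as a fall.

### Hip-angle convention

The hip angle φ_h between trunk and leg is computed with a quadrant-aware
arctangent, φ_h = φ + π − atan2(y_h, x_h − x_f), so it is continuous
through mid-stance and equals π when a vertical leg is the downward
continuation of an upright trunk.  This convention is forced by the muscle
reference angles (3.246 / 3.291 rad): any branch in which upright stance
maps near 0 would make the printed muscle rest lengths negative.

### Muscles and reflex

Each leg carries an antagonist hip pair representing rectus femoris (RF)
and hamstrings (HAM).  The muscle–tendon unit is reduced to its
contractile element: CE length is the geometric length
L_RF = L0 + ρ r0 (φ_h − φ_ref,RF), L_HAM = L0 + ρ r0 (φ_ref,HAM − φ_h)
(ρ = 0.5, r0 = 0.1 m), its velocity the exact time derivative.  CE force
is A·F_max·fl(L)·fv(v) with the bell-shaped fl (width w = 0.2 of
l_opt = 0.111 m, floor exp(ln 0.05) at the bell edge) and the Hill fv
(v_max = −12 l_opt/s, curvature κ = 5, eccentric plateau from N = 1.5;
clamped to zero beyond maximal shortening).  The net hip torque is
(F_HAM − F_RF) r0; hamstrings rotate the trunk backward.

Stimulation is a delayed, saturated leg-force reflex,
STIM = Sat[STIM0 + G·Fs(t − Δp)] with STIM0 = 0.01, Δp = 1 ms, and
first-order excitation–contraction coupling T Ȧ = STIM − A, T = 1 ms.
Saturation bounds are [0, 1] (activation's domain).  Swing-leg muscles see
zero leg force and relax to STIM0; swing legs exert no trunk torque.

### Controllers

* **FMCH** — force-modulated compliant hip, τ = G·Fs·(φ_h0 − φ_h).
* **nmF** — the neuromuscular realization above.
* **preflex** — open-loop replay of the activation traces recorded over
  one converged nmF stride, indexed by time since each leg's touchdown
  (end values held); no sensing at all.
* **adaptive nmF** — nmF plus a discrete LQR that retunes the gain pair
  U = (G_HAM, G_RF) once per step at mid-stance:
  U_k = U* − K (S_k − S*), clamped at zero, where
  S = (ẋ, y, ẏ, φ, φ̇) is sampled on the mid-stance section (stance leg
  vertical).  K solves the discrete Riccati recursion
  P ← Q + Aᵀ(P − P B (BᵀPB + R)⁻¹ BᵀP)A iterated from P0 = Q
  (default Q = R = identity; the `performance`/`balanced`/`efficiency`
  presets scale Q or R by 100), with (A, B) central-difference Jacobians
  of the step-to-step map.

## Numerics

The reflex delay makes the closed loop a delay differential equation, so
the kernel integrates with a fixed-step classical Runge–Kutta scheme
(h = 0.25 ms ≤ Δp, numba-compiled) and keeps a per-leg ring buffer of
(t, Fs) samples; every delayed lookup then lies in the already-integrated
past and is resolved by linear interpolation.  Events (touchdown, takeoff,
mid-stance crossing, falls) are detected by sign change over a step and
located by 60 bisections of a partial Runge–Kutta step, giving
root-accurate event states (the unloading leg's GRF_y at takeoff
evaluates to 0 to double precision).  Passive-phase mechanical energy is
conserved to ~10⁻¹³ per second, far inside the 10⁻⁶/s target; halving h
moves event times by < 10⁻⁷ s.  Everything is deterministic: identical
inputs give bitwise-identical event sequences.

Limit cycles are fixed points of the mid-stance return map, found by
damped least squares from shipped coarse guesses; activations are
initialized quasi-steady at the section (their 1 ms time constant is three
orders faster than a stride, so the reconstruction error is negligible).
Jacobians for stability analysis and LQR design use central differences
with step 10⁻⁴ of the state scales (gains: relative).

## Calibration — and where this implementation departs from the published constants

**FMCH.**  The compliant-hip constants are not published.  With
φ_h0 = π — the steady mid-stance hip angle — the 1 m/s solver converges to
an exactly symmetric upright gait family.  Because the FMCH torque is then
antisymmetric over the symmetric step it does no net work, so the family
is *speed-neutral*: one unit eigenvalue, all other step-map eigenvalues
inside the unit circle for G in roughly [0.3, 0.7] and [1.8, 2.2]
(parametric-flutter tongues in between).  The shipped default is
G = 0.5 m/rad, mid-window.

**nmF reflex gains.**  Two facts constrain any steady BTSLIP gait: with
massless legs the hip actuators are the only energy route, so the
cycle-averaged hip power must vanish, and the trunk-pitch balance requires
the cycle-averaged torque to offset gravity's moment — jointly forcing a
near-upright trunk and pinning the HAM:RF gain *ratio* on the 1 m/s cycle
(both balance integrals are proportional to the gains, and the two
conditions are numerically near-degenerate, ratio ≈ 1.35–1.6 depending on
magnitude).  The published gain pair (0.624, 0.936)/F_max — ratio 1.5 at
a ~4× smaller magnitude — does not close a periodic orbit in this
implementation: a brute-force search over 1080 initial conditions and the
whole (scale, ratio) plane finds no 50-step walk, the trunk drifting
backward until the gait collapses.  The package therefore ships a
deterministic calibration (`analysis.calibrate_nmf_gains`): for each
overall gain magnitude the ratio and the mid-stance state are solved
jointly for a 1 m/s period-1 orbit, and among the candidates the one that
recovers fastest from the standard trunk push is selected, giving
(G_RF, G_HAM) = (1.00, 1.37)·10⁻³ 1/N.  The printed values remain the
`ReflexParams` defaults; gait studies use the calibrated pair.

**Residual instability.**  Every nmF period-1 orbit found here carries one
weakly unstable eigenvalue (|λ| ≈ 1.04–1.06, an energy/speed mode with a
~24-step e-folding time); the trunk modes are well damped (|λ| ≈ 0.75).
Fifty-step walking from the cycle passes the ±5% speed criterion, the
trunk absorbs the −50°/s push in ~0.4 s, and the gain-adaptation layer
stabilizes the linearized map (ρ(A − BK) = 0.80), but long-horizon
robustness falls short of the published model's: after the full-size push the
walker escapes along the slow mode after ~6 s, the basin of attraction is
small, and the basin ordering across controllers is not reproduced (see
the repository's acceptance summary).  With identity LQR weights the
control is effectively free relative to the 10⁻³-scale gains, so K is
near-deadbeat and pushes beyond ~4°/s clamp the adapted gains at the zero
floor — the main practical limit of the adaptive layer here.

## Stability, perturbation and basin protocols

A run is *stable at a target speed* when the requested 50 steps complete
and every touchdown-to-touchdown mean speed is within 5% of target.  The
standard perturbation sets φ̇ to −50°/s (reading "(to −50°)" applied to an
angular velocity as °/s) at the touchdown opening the fourth stride.
Recovery time is the first moment the trunk-angle trace re-enters, and
holds for one full stride, a ±2° band around the envelope of the last
pre-perturbation stride (no published threshold exists; the band and the
envelope reading are this package's choices).  Basin-of-attraction sweeps
re-initialize (φ, φ̇) at mid-stance with the remaining section coordinates
held at limit-cycle values; a cell is stable when 50 steps complete
without a fall and the final steps return to the 5% speed band (the
acceptance comparison also reports the pure-survival reading).  The
default grid is φ ∈ [60°, 120°] × φ̇ ∈ [−200, 150]°/s at 1° × 0.1 rad/s;
the desk-scale preset (used by tests) coarsens to 5° × 0.2 rad/s
(~400 cells/model, ~10 s/model on one CPU).

## Virtual pivot point

Each loaded stance sample defines the line through its foot along its GRF.
In the trunk-fixed, CoM-centred frame (ordinate along the trunk axis) the
VPP is the least-squares point minimizing summed squared perpendicular
distances to all lines of one stride; the RMS distance is reported as the
residual and a near-singular normal matrix (parallel lines) is rejected.
On the converged nmF cycle the lines intersect well above the CoM with a
residual small against the VPP height — the pivot-point behaviour survives
the muscle dynamics.

## Synthetic reference curves

`generate_reference_curves` builds deterministic stride-indexed curves
with the qualitative structure of treadmill group data — double-humped
vertical GRF peaking near 1.1 BW, braking/propulsion horizontal GRF,
~5 cm peak-to-peak CoM oscillation, a smooth hip-torque wave, and seeded
smooth uncertainty bands.  They exist solely to exercise the
comparison/plot API; they are not measurements, and tests passing against
them say nothing about agreement with real gait data.

## Problem sizes

Default studies run at desk scale on one CPU: limit-cycle fits take a few
map evaluations (< 1 s after JIT compilation), recorded cycles span ~9
strides, perturbation runs 50 steps, and basin sweeps use the coarse
preset.  The full-resolution basin grid (~21 000 cells/model) is exposed
but intended for long unattended runs.

## Known limitations

* Massless legs: no impact losses, no swing dynamics; duty factors are
  higher and steps shorter/faster than human walking at the same speed
  (stride ≈ 0.47 s, ≈ 0.47 m at 1 m/s), and the CoM vertical excursion is
  correspondingly small (~2.2 cm).
* The printed reflex gain pair does not walk here (see Calibration); all
  quantitative robustness results inherit the weakly unstable energy mode.
* Single speed: the calibrations target 1 m/s; other speeds need
  re-calibration.
* 2-D, rigid flat ground, no noise; all results are deterministic.
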