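# Methods

`lvsa` couples a reduced-order contracting left ventricle (LV) to a 1D
model of the systemic arteries (SA) with structured-tree vascular beds,
and reproduces a baseline haemodynamic state plus four pathological
scenarios and their ventricular-arterial coupling indices. This note
records the model, its assumptions, the numerical choices, and what the
synthetic study conditions do and do not establish.

## The arterial network

The large arteries are a rooted tree of 24 tapered elastic segments
(aorta in serial pieces; head, arm, visceral and leg branches). Each
segment carries the cross-sectional-area-averaged equations

    A_t + Q_x = 0,
    Q_t + (Q^2/A)_x + (A/rho) P_x = -(2 pi nu R / delta*) (Q/A),

closed by the tube law `P - P0 = (4/3)(Eh/r0)(1 - sqrt(A0/A))` with the
exponential wall-stiffness law `Eh/r0 = k1 exp(k2 r0) + k3`. All
computation is internal CGS; mmHg/mL conversions happen at I/O. The
default geometry table (`data/network24.csv`) and the constants
k1 = 2x10^7 g s^-2 cm^-1, k2 = -22.53 cm^-1, k3 = 8.65x10^5 g s^-2 cm^-1,
rho = 1.055 g cm^-3, mu = 0.049 g cm^-1 s^-1 follow the standard
structured-tree systemic-artery model this family of solvers descends
from. Within a segment the unstressed radius tapers exponentially,
r0(x) = r_top (r_bottom/r_top)^(x/L), which keeps Eh/r0 smooth.

A note on counting: a rooted tree in which every internal node has
exactly two daughters always has an odd number of segments, so a
24-segment tree necessarily contains serial connections. The shipped
table has three (a thoracic-aorta split and the two iliac-femoral
transitions); the junction solver treats a serial connection as the
one-daughter case of the same Newton system.

The boundary-layer width defaults to the Womersley estimate
`delta* = sqrt(nu T / 2 pi)` (~0.08 cm at T = 0.9 s).

The external pressure P0 is the reference at which vessels sit at their
unstressed area. The run configuration sets it to 50 mmHg, fixed once by
a DC balance: the structured-tree beds (below) have a total Poiseuille
resistance of ~0.54 mmHg s mL^-1, so at the baseline cardiac output
(72.6 mL per 0.9 s beat) the mean arterial pressure is
P0 + R_dc * CO ~ 93 mmHg, the textbook normal. P0 is not adjusted
against any waveform feature.

## Structured-tree vascular beds

Each terminal segment feeds an asymmetric binary tree of small vessels:
daughters scale by (alpha, beta) derived from the radius exponent xi
(`r_p^xi = r_d1^xi + r_d2^xi`, baseline xi = 2.76) and the squared
daughter ratio gamma (default the literature asymmetry 0.41, stored
internally as gamma = 1/0.41 >= 1). A vessel with radius below
r_min = 100 um is a leaf; lengths are 50 radii. Root impedance is the
linearized Womersley transmission-line solution per vessel, combined in
parallel at bifurcations from the leaves (terminal impedance zero) to
the root, evaluated on the lattice of distinct (alpha^j beta^k) radii
with path-count multiplicities so beds with ~10^5 vessels cost
milliseconds. At omega = 0 this reduces exactly to the series/parallel
Poiseuille resistance. The periodic impulse response z(t) is the inverse
real DFT of the spectrum; terminal pressure is the periodic convolution
P - P0 = sum_k z(k dt) Q(t - k dt) dt over one period.

Lowering xi to 2.4 at fixed gamma prunes the trees (rarefaction): with
the default beds the total vessel count falls by ~71%, and every bed's
DC resistance rises. Note that raising r_min *lowers* the DC resistance
in this model — truncating a tree with zero leaf impedance removes the
dominant small-vessel series resistance — so r_min is not a resistance
knob in the intuitive direction.

## The 1D solver

Richtmyer two-step Lax-Wendroff on per-segment grids sized so that the
rest-state CFL number is <= 0.6 at the working time step (runtime abort
above 1.0). The taper source is discretized in flux-gradient form, and a
well-balanced correction subtracts the constant one-step residual of the
quiescent state, making "no flow, A = A0, P = P0" an exact discrete
fixed point even on tapered grids. Boundary closures are conservative
ghost half-cell continuity updates: the boundary node at each segment
end owns a half cell whose area advances from the same (rest-corrected)
interface flux the interior used plus the physical boundary flow
averaged over the step, so every control volume is in discrete flux
form and the network conserves mass to round-off (a characteristic
extrapolation closure was tried first and rectified O(dx * taper) mass
errors of several percent of the stroke volume per period). The
physical condition then closes the boundary flows:

* inlet: prescribed Q; the area follows explicitly from the half-cell
  continuity;
* bifurcations and serial junctions: flow conservation plus static
  pressure continuity, Newton on the boundary flows (pressure
  continuity is static, not total — the difference is second order in
  velocity);
* terminals: the impedance convolution combined with the half-cell
  continuity, scalar Newton on the outflow.

## The reduced left ventricle

The chamber is an incompressible thick-walled sphere (unloaded inner
radius 2.70 cm, outer 3.758 cm: cavity ~82 mL, wall ~140 mL). The wall
carries the Holzapfel-Ogden passive law evaluated for the equibiaxial
tangent-plane kinematics of a sphere (lambda_theta = lambda_phi = lam,
lambda_r = lam^-2) with fibers and sheets uniformly distributed in the
tangent plane (the cos^2 projection averages to 1/2; the I8fs shear term
vanishes identically in these kinematics, though afs is retained so the
stiffer-myocardium scenario scales the same constant set as the source
model). Cavity pressure is the radial equilibrium integral

    P = int_{ri}^{ro} (sigma_tt + sigma_pp - 2 sigma_rr + T_act) dr / r

with 64-point Gauss quadrature across the wall and the shell radii
mapped incompressibly. Active tension is `T0 * twitch(t) * max(0, 1 +
beta_length (lam - 1))` with a normalized unimodal twitch (product of a
rising and a falling exponential saturation; defaults tau_rise 0.12 s,
tau_fall 0.06 s, duration 0.42 s). The rise constant puts the tension
peak at mid-systole, as in the reference active-stress time course, and
sets the ejection spread (hence the peak aortic flow); the twitch must
be essentially over by ~0.4 s — if tension persists longer, ejection
under a stiffened (fast-decaying) afterload creeps along the windkessel
decay, inverting the stroke-volume response and corrupting the
end-systolic points. The calibration therefore clamps its
ejection-duration search at 0.44 s; with that clamp the baseline
ejection time calibrates to ~205 ms against the 220 ms target, a
residual of the reduced chamber's volume-limited ejection that is
accepted rather than hidden.

`beta_length = 7` encodes the Frank-Starling steepness (tension rising
~2x over stretch 1.0 -> 1.15). It sets the chamber's intrinsic
end-systolic stiffness, ~1.8 mmHg/mL here — inside the normal human
E_S range. Much smaller values flatten the end-systolic pressure-volume
relation (ESPVR) into clinical nonsense; much larger ones make ejection
volume-limited and uncalibratable. This replaces the full myofilament
ODE model: the scenarios only exercise T0 scaling, timing, and length
dependence, all of which the twitch exposes.

Calibration (`calibrate_baseline`) matches the study targets
EDV = 142.4 mL at EDP = 8 mmHg, SV = 72.6 mL, ejection time 220 ms:
the passive stiffness scale has a closed-form solution (pressure is
linear in the a-type constants at fixed kinematics); T0 follows by a
secant iteration on the stroke volume of a warm-started coupled cycle,
with a clamped proportional update of the twitch duration for the
ejection time. The scale multiplying the published constitutive
constants is ~0.05: the spherical reduction concentrates strain at the
inner wall relative to a real ellipsoidal LV, and the scale absorbs that
geometric mismatch; it is the calibrated quantity, not a literature
value.

## Coupling

Per arterial step (dt = T/2048 by default) during systole the interface
solves the outflow-tract momentum balance

    P_lv(V - (q_prev + Q) dt/2, t) - P_sa(Q) = L (Q - q_prev)/dt

by bracketed root finding: the arterial side maps a trial inflow to an
inlet pressure through the inlet characteristic, the chamber side maps
the implied volume change to a cavity pressure, and
L = rho l_eff / A_root = 0.65 g cm^-4 (blood-column inertance of a 3 cm
outflow tract at the 4.9 cm^2 aortic root) carries the inertia the
quasi-static chamber otherwise lacks. There is no resistive
transvalvular drop. The valve opens when cavity pressure reaches root
pressure and closes when the solved flow falls to zero; without the
inertance, ejection ends in a long low-flow tail whenever the afterload
decays in step with the twitch. Diastole is uncoupled: the network runs
with zero inflow and the chamber refills along a prescribed smooth
cosine ramp to the EDV at the fixed 8 mmHg EDP (no mitral valve or
atrium). The arterial state is initialized for four periods with a
prescribed sin^p systolic pulse (peak 500 mL/s, 300 ms, 72.6 mL) before
coupling; coupled cycles repeat until the maximum relative probe
pressure change between consecutive cycles is < 1% (typically by cycle
2-3).

## Scenarios and indices

case1 doubles k3 in the large arteries only (beds keep the baseline wall
law); case2 lowers xi to 2.4; case3 doubles the a-type passive
constants; case4 raises T0 by 33%. The iso variants drive the modified
network with the baseline coupled interface flow instead of the chamber.
Indices: peak wall-averaged active tension, peak LV/aortic pressures,
peak interface flow, SV (interface flow integral), stroke work (shoelace
area of the P-V loop, in cJ; 1 mmHg mL = 1.33322x10^-4 J), ejection
time, EF, per-probe peaks/troughs/timing/backflow. E_A = end-systolic LV
pressure over SV; E_S is the least-squares slope through the
end-systolic (V, P) points of baseline, case1 and case2 (end-systole
operationalized as aortic-valve closure).

## Problem sizes and numerics

The reference model uses 8192 steps per period; this package defaults to
2048 (about 0.44 ms) with CFL-derived grids (~450 nodes network-wide),
which keeps a full calibrated three-scenario study in minutes on one
core while staying within ~1% of a grid-refined run on smooth cases.
Junction Newton tolerance 1e-12 relative; exchange tolerance 1e-6
relative on the interface flow; quadrature and root-finding tolerances
as documented per function. Degenerate inputs (zero contractility, zero
convergence threshold, constant waveforms) follow documented fallbacks
(valve never opens; non-convergence warning; earliest-sample peak time).

## What the synthetic conditions do not show

The study conditions are the package's own reconstruction: the geometry
table and tree parameters follow the cited-lineage defaults, not a
patient; the reduced spherical chamber has no regional wall motion,
fiber strain field, intraventricular flow, pericardium, atrium or mitral
valve; diastolic filling is prescribed rather than pressure-driven.
Pulse-pressure-sensitive quantities inherit the reconstructed bed
resistances and P0 split: the baseline pulse pressure is roughly twice
the reference (brachial ~147/63 vs 126/81 mmHg — systolic high and
trough low together), and the aortic flow-peak transit delay is
substantially shorter than the reference, because the windkessel decay
time and the reflection pattern at the operating point are set by the
reconstructed stiffness/resistance balance. Ratio- and
conservation-based quantities — EF, E_A/E_S, volume balances, vessel
counts, the directional scenario responses — are insensitive to this
and land within a few percent of the reference; absolute troughs and
transit delays are not, and are reported as such.
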