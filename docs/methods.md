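# Methods

`wingsense` models how a small set of spiking strain sensors on a flexible,
flapping insect wing can detect body rotation. The pipeline has four stages:
a structural simulation of wing strain, a linear–nonlinear spiking encoder,
sparse sensor placement (SSPOC), and a linear centroid readout of
single-spike timing. This note records the model, its assumptions, the
parameters that matter, and the choices made where the design was genuinely
open.

## Wing strain model

The wing is a thin rectangular plate — span 50 mm, chord 25 mm, thickness
0.127 mm, density 1200 kg/m³, Poisson ratio 0.3 — clamped along the base
chord and flapped about the body's longitudinal axis with a two-harmonic
stroke, θ(t) = A[sin(2π·25t) + 0.76·sin(2π·50t)], with primary amplitude
A = π/3 rad (the stroke amplitude is not a measured quantity here; its
absolute scale is later divided out by the encoder normalization). A body
rotation at a constant rate (10 rad/s unless varied) about the yaw, pitch,
or roll axis is superimposed; all rotation axes pass through the wing root.

Deflection is expanded in an assumed-modes (Rayleigh–Ritz) basis of
clamped-free beam functions spanwise × free-free functions (rigid
translation, rigid rotation about mid-chord, then elastic modes) chordwise;
default basis 6 × 5 = 30 terms. Stiffness is parameterized by Young's
modulus alone through the flat-plate rigidity D = Eh³/12(1−ν²); the
optional orthotropic multipliers (spanwise, chordwise, torsion) default
to 1. At the 3 GPa reference (stiffness factor 1) the first bending mode is
≈13.5 Hz and the first torsion mode ≈58 Hz, so the stroke drives bending
above resonance (mass-dominated) while torsion sits just above the 50 Hz
stroke harmonic. The stiffness sweep (0.7–10 GPa) moves these modes through
the stroke harmonics — the source of the strongly non-monotonic dependence
of detection accuracy on stiffness. Below 0.7 GPa the torsion mode
approaches the primary stroke frequency and the model is outside its
validated range; such moduli are rejected.

In the wing-fixed rotating frame, with (p, q, r) the spanwise, chordwise
and normal components of the total angular velocity, the plate is driven
by:

- **Inertial loading.** Euler and centrifugal terms give a normal
  acceleration a_n = (ṗ + rq)·η + (rp − q̇)·x at in-plane position
  (x, η) (η measured from mid-chord). For the flat unfeathered wing this
  has zero chordwise gradient for every rotation axis through the root —
  the Euler and centrifugal contributions cancel exactly (verified against
  an independent inertial-frame finite-difference computation) — so inertial
  forcing bends but never twists the wing.
- **Quasi-steady aerodynamics.** Blade-element normal drag
  −½ρ_air·C_N·v_n|v_n| with C_N = 1.5, and rotational (Kramer) lift
  ρ_air·C_R·c²|U|·p applied at the quarter chord with C_R = π/2 — a net
  force plus a pitching moment, implemented as the equivalent
  chordwise-linear pressure. The rotational term is the rotation-to-twist
  channel: yaw contributes p = Ω sinθ, pitch p = Ω cosθ, and roll p = 0
  exactly. Roll is instead detected through the 2θ̇Ω modulation of the
  quadratic drag (the flapping rate is shifted by the roll rate). The drag
  linearized about the rigid motion also damps the elastic response
  (diagonal modal approximation); without it the torsion resonance leaves
  the small-deflection regime.
- **Parametric stiffness.** Centrifugal softening of out-of-plane
  deflection, −(p² + q²) per unit modal mass, nearly cancelled by geometric
  stiffening from spanwise centrifugal tension (Southwell-type term,
  assembled exactly from the in-plane stress field) — the familiar reason
  flapping blades do not buckle.

The decoupled-by-mass modal system with time-varying damping and stiffness
is integrated by the average-acceleration Newmark scheme at the 0.1 ms
output step (unconditionally stable for this linear time-varying problem);
six settle wingbeats are simulated and discarded, and in the pipeline they
double as real history for the encoder's temporal filter so the first
retained wingbeat carries no start-up edge. Divergence (deflection far
beyond the span, or non-finite states) raises a convergence error naming
the stiffness. Surface normal strain ε = −(h/2)·∂²w/∂x² (spanwise; chordwise
analogous) is evaluated analytically from the basis on the 26 × 51, 1 mm
sensor lattice. Because torsion is nearly a linear-in-span twist, its
spanwise-curvature signature concentrates where the clamped root forces the
twist rate to turn over — the wing-base corners, which is where
rotation-induced strain differences peak.

**Noise.** Independent Gaussian noise is added per 0.1 ms time step to the
flapping angular rate (sd = 2% of the peak stroke rate) and to the rotation
rate (sd = 1% of the rate; omitted for the roll task, whose rotation shares
the flapping axis). White rate noise is strongly attenuated by the modal
dynamics and the encoder's band-pass filter, so downstream variability is
dominated by spike-generation stochasticity — measured: strain-noise-induced
first-spike jitter is ≈0.1 ms against multi-millisecond spike-sampling
jitter. The gust disturbance used by the robustness experiments is the same
white-noise mechanism with sd expressed as a fraction of the 10 rad/s
reference rate, applied in both conditions about the probed axis.

## Spiking encoder

Each site convolves its strain with f(t) = cos(2πω(t+τ))·exp(−(t+τ)²/δ²)
(ω = 1/2π ms⁻¹, τ = 5 ms, δ = 4 ms; a band-pass around ≈160 Hz peaking
5 ms in the past). The kernel is reported on lags [−τ−3δ, −τ+3δ]; the
convolution uses the lags ≤ 0 only (strictly causal, no latency; the
dropped acausal tail has |f| ≤ 0.06). Filtered strain is divided by a
single constant, fixed once per study so that max |g| over all sensors and
times equals exactly 1 for a noise-free flapping-only run at the 3 GPa
reference, and reused for every stiffness and condition; the neural
threshold range β ∈ [0.05, 0.7] is therefore a fraction of the reference
maximum. The firing probability per step is N(g) = 1/(1 + e^{−α(g−β)})
with α = 50; a spike occurs when N exceeds a fresh Uniform(0,1) draw,
subject to a 15 ms absolute refractory period (next spike allowed at
t_prev + 15 ms, closed boundary), which holds sensors to ~1–2 spikes per
40 ms wingbeat. The classifier input is the time to the first spike within
each wingbeat at 0.1 ms precision (sample j reported as (j+1)·0.1 ms, so 0
unambiguously means "no spike"). The pipeline uses a fused strain→first-spike
kernel that draws uniforms only where the probability is above numerical
zero; its sampling law matches the reference path (checked distributionally)
though the random streams differ.

## Sensor selection (SSPOC)

Training features are z-scored per sensor (zero-variance sensors get unit
scale), reduced by PCA to m = 3 components Ψ, and LDA in the reduced space
gives the discriminant direction(s) w. Sensor weights solve

  min_s λ‖s‖₁ + (1−λ)‖s‖₂  subject to Ψᵀs = w  (two classes)

with λ = 0.9 and the Euclidean (non-squared) ‖·‖₂; the multi-class variant
relaxes the constraint to |Ψᵀs − w| ≤ ε elementwise with ε = 10⁻⁶, applied
columnwise to the (classes−1) discriminant directions, and sensors are
ranked by row-wise ℓ₂ norm. The program is solved by ADMM with closed-form
projection (Ψ has orthonormal columns) and the composed
soft-threshold/block-shrinkage proximal map; the returned point is
projected onto the constraint set, so the reported residual is at solver
precision. The solver is validated against the λ = 0 minimum-norm closed
form and a refined-grid brute-force minimizer on small instances. The k =
10 sensors with the largest aggregated |weight| are kept (ties break to the
lower grid index). When a cell's features carry no class information at all
(e.g. every first-spike time locked to the same refractory cadence), the
subspace fit degenerates; the pipeline then scores an arbitrary single
sensor, which lands at chance through the ordinary readout.

## Readout and evaluation

A stratified, seeded 90/10 split is made per data set. A fresh LDA
projection is fit on the non-standardized training features of the selected
sensors only (pooled covariance with a 10⁻⁶ ridge — first-spike features
are often constant); two-class decisions use the midpoint of the projected
class centroids, multi-class the nearest centroid. Accuracy is the held-out
fraction correct; experiment-level numbers are means ± sd over replicate
data sets (fresh simulation and spiking per replicate). Sensor dropout
refits the readout on the surviving sensors; the disturbance experiment
keeps the clean-data sensor choice and refits only the readout on disturbed
data.

## Synthetic surrogate

`surrogate_strain` provides an analytic stand-in for the plate solve: a
quadratic-in-span bending pattern plus a corner-antisymmetric twist pattern,
driven by the two stroke harmonics, with class-dependent twist amplitude
and optional white noise. It reproduces the *structure* the downstream
stages assume (periodic bending + small class-dependent twist) but none of
the resonant dynamics, so passing surrogate-based tests demonstrates the
correctness of the encoder/selector/readout machinery, not the fidelity of
the strain physics.

## Problem sizes

Printed-condition defaults are 3 s (75 wingbeats) per condition, 10 spike
repeats (1,500 observations per two-class optimization), k = 10 sensors,
and 20 replicate data sets. Parameter sweeps in the acceptance script and
test suite use 30-wingbeat simulations, 2–10 replicates per cell, and the
7 × 8 stiffness-by-threshold grid; these sizes were chosen as the package's
desk-scale defaults and are stated next to each experiment.

## Known limitations

- The plate dynamics are a reimplementation of the cited model class, not
  of the original solver; absolute accuracy levels inherit that gap. In
  particular the model's yaw twist forcing is proportional to
  |θ̇|·Ω·sinθ — in quadrature with the stroke speed — so yaw detection
  reaches only ~60–65% on replicate average (single data sets peak near
  70–85%) rather than the reported ≈98%, while roll (95–100%) and pitch
  (80–90%) detection are strong. The printed spanwise flexural
  stiffness cannot be reconciled with the printed geometry under the
  flat-plate formula; following the stiffness-by-modulus-only convention
  places the stroke harmonics among the structural resonances, which
  reproduces the non-monotonic accuracy phenomenology but breaks any
  quasi-static strain-vs-stiffness monotonicity (it holds only on the
  stiff, post-resonance part of the range).
- Geometric nonlinearity is absent: simulated deflections at the softest
  stiffnesses exceed the small-deflection regime, and deflection-coupled
  rotation forces (a plausible additional yaw channel) are not represented.
- Aerodynamics is quasi-steady blade-element theory with constant
  coefficients; no wake, added-mass, or unsteady circulation effects.
- Sensors are identical, single-filter, and noise-free apart from the
  probabilistic spike draw; only first-spike times are decoded.
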