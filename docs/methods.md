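# Methods

## Overview

`emgstiff` estimates sagittal-plane knee and ankle joint angles, angular
rates, joint torques and ankle quasi-stiffness from surface-EMG envelopes and
joint-angle measurements.  The plant is an EMG-driven, three-segment
(thigh-shank-foot) musculoskeletal model; the estimator is a square-root
cubature Kalman filter (SCKF) chosen because the plant is nonsmooth (the
signum-law viscous torque, clipped activations) and strongly nonlinear, which
rules out Jacobian-based observers.  Quasi-stiffness — the derivative of the
joint torque with respect to the joint angle — is reconstructed from the
filtered states, which exposes stiffness changes caused by antagonist
coactivation that are invisible to torque measurements alone.

## Kinematics and muscle geometry

The global frame sits at the hip (x anterior, y superior, z mediolateral).
Hip, knee and ankle are sagittal hinges; the hip angle is an exogenous input.
The upper ankle joint is a single fixed hinge whose axis is tilted relative
to the shank by `alpha_TC_tla` (tibia long axis vs. axis, default 84°) and
`alpha_TC_fml` (foot mid-line vs. axis, default 96°).  Foot-fixed points map
into the knee frame through a homogeneous transform
`T(phi) = Trans(x_t, y_t) · Ry(gamma) · Rx(beta) · Rz(phi)` with
`beta = alpha_TC_fml − 90°`, `gamma = 90° − alpha_TC_tla`, and all muscle
geometry is evaluated on the sagittal projection of the 3-D points.  Because
the true rotation axis is tilted, the projected centre of rotation moves with
the ankle angle; it is recovered numerically at each posture by rotating two
foot-fixed markers through ±1 mrad and intersecting the perpendicular
bisectors of their displacement chords.

Six muscles are modelled: RF, HAMS (alias ST), VM, GAS, SOL, TA.  Each is a
polyline of nodal points (origin, via/retinaculum points, insertion) fixed in
body frames.  Nodal coordinates, axis angles and all anthropometry are
configuration data; the shipped values are plausible literature-style
placeholders (lever arms 3-5 cm at the ankle, 2-5 cm at the knee), **not**
canonical values, and can be replaced wholesale from a YAML file.  Lever
arms are perpendicular distances from the projected rotation centre to the
muscle's effective line of action (for TA, the retinaculum node in the shank
to the insertion in the foot).  Musculotendon lengths are summed projected
segment lengths.

Lengths and lever arms are tabulated offline on 1° grids over the joint
ranges (hip −20…150°, knee 0…100°, ankle −60…20°) and approximated by
fourth-order polynomials — univariate for uniarticular muscles, a bivariate
quartic surface for the biarticular GAS (knee, ankle) and RF/HAMS (hip,
knee) lengths, so both partial derivatives needed for biarticular
contraction velocities come from one representation.  Worst-case fit
residuals (stored with each table) are below 0.35 mm for every muscle.
Lever-arm polynomials are fitted only for the knee and ankle: the hip torque
is an unknown exogenous quantity that never enters the model, so hip lever
arms are not needed.  The knee range stops at 100° because beyond ~107° the
straight patellar line of the fixed nodal points crosses the knee centre —
an artefact of fixed via points, not anatomy.  Out-of-range queries raise by
default; inside the filter loop they are clamped to the table edge, because
cubature points may transiently leave the admissible range.

A second, virtual-displacement lever arm `r = ∂l_MT/∂φ` is provided for
cross-validation only.  The two constructions agree in sign and shape over
the range but show an offset; the distance-to-line values are the ones used
in the dynamics.

## Muscle dynamics

Each muscle contributes two states.  Activation follows first-order bilinear
dynamics `da/dt = (s − a)(c1 s + c2)` with `tau_act = 15 ms` and
`tau_deact = 60 ms`, so activation is faster than deactivation and `a → s`
under a constant envelope.  The normalised isometric force `F̄isom` is a
first-order activation-to-force development lag (`tau_force = 40 ms`).
Tendon force uses a rigid tendon:

    F_T = F_max · F̄isom · f_l(l_M) · f_v(v_M),   l_M = (l_MT − l_T)/cos αp

with a Gaussian force-length factor (width 0.35 in normalised length) and a
hyperbolic Hill force-velocity factor (shortening branch vanishing at
−v_max, eccentric branch saturating at 1.5).  The force-length factor sits
inside the tendon force rather than inside the contraction-state target so
that tendon force depends on the angle *instantaneously*: quasi-stiffness is
defined at frozen muscle states, and the force-length slope is precisely the
mechanism by which coactivation raises joint stiffness.  Tendon length and
optimal fibre length are derived per muscle from the neutral-posture MTC
length (tendon ratio 0.5; fibre at 0.85 of optimal length at neutral, i.e.
on the ascending limb).  The ascending-limb operating point is a deliberate
choice: there the force-length slope is positive and steep enough that
antagonist coactivation stiffens the joint faster than the lever-arm
geometry destiffens it, which is the experimentally observed behaviour.
Passive muscle elasticity and viscosity are *not* in the tendon force; they
are lumped at joint level (below) to avoid double counting.

## Rigid-body dynamics

The three-segment chain follows the Euler-Lagrange form
`M(q) q̈ + D(q, q̇) q̇ + k(q) = τ` with generalised coordinates
q = (hip, knee, ankle), flexion/dorsiflexion positive.  Segment
anthropometry defaults to relative data for a 75 kg, 1.75 m adult.  Because
every centre of mass is a short sum of terms `a·e(θ + offset)` with θ linear
in q, M(q) is a constant plus a few cosine terms; its q-derivatives are
therefore analytic, and D uses the Christoffel combination
`d_kj = ½ Σ_i (∂m_kj/∂q_i + ∂m_ki/∂q_j − ∂m_ij/∂q_k) q̇_i`, which makes
(Ṁ − 2D) skew-symmetric.  A finite-difference fallback for ∂M/∂q is kept as
an independent cross-check.  The hip row is eliminated: the hip angle, rate
and acceleration are inputs, and they enter the knee/ankle equations through
the coupling columns of M and D.

Joint torques sum four contributions, `τ = τ_T + τ_E + τ_V + τ_ext`:

- **Active** `τ_T = Σ sgn_i r_i F_i`.  The sign of each muscle's torque is
  derived from its geometry (a muscle that shortens as the angle grows pulls
  the joint in the direction of increasing angle), giving TA positive and
  SOL/GAS negative at the ankle.
- **Elastic** double-exponential laws per joint, with biarticular coupling
  terms in the neighbouring joint angles.  In this package's flexion-positive
  knee coordinate the extension stop is carried by the first exponential
  (`c1k = −14 rad⁻¹`); the additional subtracted exponential `τ*` is kept as
  a mild shaping term because with this coordinate direction it cannot act
  as a restoring stop (with a dominant `τ*` the passive knee torque becomes
  anti-restoring at full extension and the dynamics escape in finite time).
  All coefficients are package defaults of plausible magnitude: a few N m at
  mid-range, steep barriers at the range limits, a hanging equilibrium at
  ~5-15° knee flexion and ~20-25° plantar flexion.
- **Viscous** power law `K sgn(q̇)|q̇|^n` (knee K = 2.0, ankle K = 0.5,
  n = 1.1).  The printed law is a magnitude along sgn(q̇); the assembly
  applies it with a minus sign so the element dissipates.
- **External** GRF torque `((p_GRF − o_j) × f_GRF) · e_z`, zero in the
  default free-swinging protocol.

The assembled 16-state model is x = (knee, ankle, knee rate, ankle rate, six
activations, six normalised forces), with the 15-channel input (six EMG
envelopes, hip angle/rate/acceleration, CoP, GRF).  The measurement equation
selects the two joint angles.

## Square-root cubature Kalman filter

The SCKF implements the third-degree spherical-radial cubature rule: 2n
points at ±√n along the coordinate axes with uniform weights 1/(2n) — no
negative weights, which is what makes the square-root formulation sound.
The covariance is propagated exclusively as a lower-triangular factor S with
P = S Sᵀ, updated via QR triangularisation with a diagonal-sign convention
for cross-platform determinism.  The Kalman gain solves
`K (S_yy S_yyᵀ) = P_xy` with two triangular solves; no matrix is ever
explicitly inverted.  The filter transition is the explicit-Euler
discretisation of the plant at the estimator rate (100 Hz, the orientation
sensor rate).  Cubature points are clamped before propagation (activations
to [0, 1], force states to [0, 1.5]); clamp events are counted and reported.
Prediction uses the input held over the step leading to the current sample;
the initial sample receives a measurement-only correction.

Default noise configuration (standard deviations): process — 5·10⁻⁴ rad
(angles), 5·10⁻³ rad/s (rates), 3·10⁻³ (muscle states); measurement —
0.3° per angle channel; initial — 0.01 rad, 0.1 rad/s, 0.05 (muscle
states).  The process noise is mildly inflated over the truth injection to
absorb the Euler-vs-RK4 discretisation mismatch.

## Signals

Raw sEMG (1500 Hz) is band-pass filtered 10-500 Hz (4th-order Butterworth),
rectified, low-pass filtered at 6 Hz to a linear envelope (the corner is a
package choice; conventional for EMG-driven models), normalised to MVC,
clipped to [0, 1] and polyphase-resampled to 100 Hz.  Causal filtering is
the default because the estimator is an on-line method; zero-phase is
available for offline runs.  Hip rate and acceleration are produced from the
hip angle by a band-limited differentiator
`G(s) = s / ((s/30 + 1)(s/300 + 1)²)` (bilinear-discretised, applied twice
for the acceleration): an ideal differentiator below ~30 rad/s with bounded
high-frequency gain.

## In-silico protocol and what it shows

The forward simulator is the package's ground truth: hip angle
20°·sin((π/2 rad/s)·t), all joints starting at zero, muscles activated in
5 s blocks separated by 5 s rests over 30 s — dorsiflexor block (TA 0.25),
plantar-flexor block (SOL 0.20, GAS 0.12), antagonist coactivation block
(TA 0.25, SOL 0.15, GAS 0.08), and a flexor-dominant knee block (RF 0.10,
VM 0.06, HAMS 0.20; extensor dominance would park the knee on its extension
stop).  Block envelopes use 0.15 s smoothstep transients.  Truth integrates
with fixed-step RK4 at 10× the estimator rate, so the filter's Euler model
faces a genuine discretisation mismatch.  White Gaussian noise is injected
into the states once per estimator step (2·10⁻⁴ rad angles, 2·10⁻³ rad/s
rates, 10⁻³ muscle states) and into the angle measurements (0.3°).  Under a
fixed seed the record is bit-reproducible (content-hashed).

With the default configuration the SCKF tracks the truth with RMS angle
errors of roughly 0.1-0.2° and RMS rate errors of roughly 0.05-0.25 rad/s
(seed-dependent), and the reconstructed joint torques track the truth
torques to a few percent of their dynamic range.  The synthetic data emulate
MVC-normalised envelopes, block activations and noisy angle measurements;
they do **not** emulate EMG crosstalk, electrode artefacts, soft-tissue
sensor movement, model-to-subject anthropometric mismatch or ground contact,
so passing these tests demonstrates correctness of the estimator machinery
under the stated model class, not field accuracy on human data.

## Quasi-stiffness

Active ankle quasi-stiffness applies the product rule to τ = Σ sgn r_i F_i:
the lever-arm derivative comes analytically from the quartic tables, and the
tendon-force derivative is evaluated with activation and force states frozen
(stiffness is an instantaneous mechanical property), flowing through the
force-length slope and, when the joint moves, the force-velocity slope via
the angle dependence of the length partials (perturbation step for the
finite-difference cross-check: 10⁻⁴ rad).  Reported torque and stiffness use
the clinical plantarflexion-positive convention so that a restoring joint
has positive stiffness; the passive elastic slope is reported as a separate
additive column, and the total (active + passive) is also emitted since it
is ambiguous which variant published figures include.  A moving-average
smoother (default 51 samples = 0.5 s) accompanies the raw series, whose
short-lived peaks can reach unphysiological values when noisy envelopes hit
the contraction dynamics.

## Numerical choices and limitations

- Explicit Euler inside the filter (as the estimator design prescribes);
  RK4 truth; energy drift of the torque-free chain scales linearly with the
  Euler step (verified).
- QR-based triangularisation with non-negative diagonal; singular innovation
  factors raise instead of producing NaNs.
- Geometry table clamping inside the filter is logged, not silent.
- Elastic-torque exponentials are overflow-guarded (exponent cap 50) and
  raise a diagnostic rather than returning infinities.
- Rigid tendons: series-elastic stiffness is absent, so absolute stiffness
  magnitudes are set by the force-length slope and the chosen operating
  point rather than tendon compliance.  Elastic-tendon variants are out of
  scope.
- Single fixed ankle axis; no inversion/eversion, no subtalar joint, no
  ground-contact or gait-phase modelling.
- All anatomical constants are placeholders; quantitative agreement with a
  specific subject requires configuring measured geometry and parameters.
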