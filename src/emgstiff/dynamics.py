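"""Three-segment Euler-Lagrange dynamics and the 16-state plant model.

Generalised coordinates are q = (hip, knee, ankle) in radians with the sign
convention: positive hip = flexion (thigh anterior), positive knee = flexion
(shank posterior), positive ankle = dorsiflexion.  Absolute segment angles
measured from the downward vertical are theta1 = q1, theta2 = q1 - q2 and,
for the foot (whose anterior axis is perpendicular to the shank at zero),
theta3 = q1 - q2 + q3.  The ankle hinge is treated as perpendicular to the
sagittal plane for the rigid-body dynamics; the tilted anatomical axis enters
only through the muscle geometry tables.

The hip angle and its derivatives are exogenous inputs: the equations of
motion are reduced to the knee/ankle rows, with the hip entering through the
inertial and Coriolis coupling terms.

Joint torque composition: tau_j = tau_T (muscle) + tau_E (elastic) + tau_V
(viscous) + tau_ext (ground reaction).  The viscous element K sgn(q̇)|q̇|^n is
applied with a leading minus sign in the assembly so that it dissipates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kinematics as kin
from . import muscle as mus

GRAVITY = 9.81

# state layout: (knee, ankle, knee rate, ankle rate, a x 6, F_isom_bar x 6)
N_STATES = 16
# input layout: (s x 6, hip, hip rate, hip accel, CoP xyz, GRF xyz)
N_INPUTS = 15

IDX_ANGLES = slice(0, 2)
IDX_RATES = slice(2, 4)
IDX_ACT = slice(4, 10)
IDX_FORCE = slice(10, 16)

#: measurement matrix selecting the two joint angles, y = C x
C_MEASURE = np.zeros((2, N_STATES))
C_MEASURE[0, 0] = 1.0
C_MEASURE[1, 1] = 1.0


@dataclass
class Segment:
    """Mass (kg), sagittal COM offset in the segment frame (m), moment of
    inertia about the COM (kg m^2) and segment length (m)."""

    mass: float
    com: tuple[float, float]
    inertia: float
    length: float

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.inertia <= 0:
            raise ValueError("segment mass and inertia must be positive")


@dataclass
class SegmentParams:
    """Anthropometry of thigh, shank and foot.

    Defaults follow relative segment data for a 75 kg, 1.75 m adult (masses
    and COM locations as fractions of body mass and segment length).
    """

    thigh: Segment = field(
        default_factory=lambda: Segment(10.5, (0.0, -0.18), 0.21, 0.41)
    )
    shank: Segment = field(
        default_factory=lambda: Segment(3.25, (0.0, -0.19), 0.05, 0.43)
    )
    foot: Segment = field(
        default_factory=lambda: Segment(1.0, (0.10, -0.03), 0.005, 0.26)
    )


@dataclass
class PassiveTorqueParams:
    """Double-exponential elastic and power-law viscous joint torques.

    Knee:  tau2E = exp(a1k + b1k q1 + c1k q2 + d1k q3)
                 - exp(a2k + b2k q1 + c2k q2 + d2k q3) + ek - exp(fk + gk q2)
    Ankle: tau3E = exp(a1a + b1a q2 + c1a q3) - exp(a2a + b2a q2 + c2a q3) + da

    All coefficients are package defaults of plausible magnitude (torques of a
    few N m at mid-range, steep barriers at the range limits), not canonical
    values; angles in radians, torques in N m.
    """

    a1k: float = 0.5
    b1k: float = 0.3
    c1k: float = -14.0
    d1k: float = 0.5
    a2k: float = -12.0
    b2k: float = -0.3
    c2k: float = 8.0
    d2k: float = -0.2
    ek: float = -1.0
    fk: float = -2.0
    gk: float = -2.0
    a1a: float = -3.5
    b1a: float = -0.3
    c1a: float = -8.0
    a2a: float = -4.0
    b2a: float = -1.0
    c2a: float = 18.0
    da: float = 0.0
    k_v_knee: float = 2.0
    n_v_knee: float = 1.1
    k_v_ankle: float = 0.5
    n_v_ankle: float = 1.1

    def __post_init__(self) -> None:
        if self.k_v_knee < 0 or self.k_v_ankle < 0:
            raise ValueError("viscous gains must be non-negative")
        if self.n_v_knee <= 0 or self.n_v_ankle <= 0:
            raise ValueError("viscous exponents must be positive")


@dataclass
class GroundReaction:
    """Ground-reaction force (N) and its point of action (m), global frame."""

    p_grf: np.ndarray
    f_grf: np.ndarray

    def __post_init__(self) -> None:
        self.p_grf = np.asarray(self.p_grf, dtype=float)
        self.f_grf = np.asarray(self.f_grf, dtype=float)
        if not (np.isfinite(self.p_grf).all() and np.isfinite(self.f_grf).all()):
            raise ValueError("ground reaction components must be finite")


_MAX_EXPONENT = 50.0


def _safe_exp(x: float) -> float:
    if x > _MAX_EXPONENT:
        raise OverflowError(f"elastic-torque exponent {x:.1f} out of range")
    return math.exp(x)


# ---------------------------------------------------------------------------
# rigid-body terms
# ---------------------------------------------------------------------------

#: rows of d(theta)/dq for the three segments
_W = np.array([[1.0, 0.0, 0.0], [1.0, -1.0, 0.0], [1.0, -1.0, 1.0]])


def _body_terms(segs: SegmentParams):
    """Decompose each COM position into sum_k a_k e(psi_k + offset).

    e(psi) = (sin psi, -cos psi); a point r fixed in a segment with absolute
    angle theta satisfies R(theta) r = |r| e(theta + atan2(ry, rx) + pi/2).
    """

    def polar(r):
        return math.hypot(r[0], r[1]), math.atan2(r[1], r[0]) + 0.5 * math.pi

    l1 = segs.thigh.length
    l2 = segs.shank.length
    a1, o1 = polar(segs.thigh.com)
    a2, o2 = polar(segs.shank.com)
    a3, o3 = polar(segs.foot.com)
    # (amplitude, segment index, angle offset) per term; segment index selects
    # the absolute-angle row of _W
    return (
        (segs.thigh.mass, segs.thigh.inertia, 0, [(a1, 0, o1)]),
        (segs.shank.mass, segs.shank.inertia, 1, [(l1, 0, -0.0), (a2, 1, o2)]),
        (
            segs.foot.mass,
            segs.foot.inertia,
            2,
            [(l1, 0, 0.0), (l2, 1, 0.0), (a3, 2, o3)],
        ),
    )


class _Chain:
    """Precomputed trigonometric structure of the three-link chain.

    Since every COM is a sum of terms a e(theta_s + off), the inertia matrix
    is a constant plus a short sum of cos(delta . q + phase) times constant
    symmetric matrices, and its q-derivatives follow analytically.
    """

    def __init__(self, segs: SegmentParams) -> None:
        Mc = np.zeros((3, 3))
        B, delta, phase = [], [], []
        grav_coef, grav_row, grav_off = [], [], []
        for mass, inertia, widx, terms in _body_terms(segs):
            Mc += inertia * np.outer(_W[widx], _W[widx])
            for t, (a, si, off) in enumerate(terms):
                Mc += mass * a * a * np.outer(_W[si], _W[si])
                grav_coef.append(mass * a)
                grav_row.append(_W[si])
                grav_off.append((si, off))
                for a2, sj, off2 in terms[t + 1 :]:
                    B.append(
                        mass
                        * a
                        * a2
                        * (np.outer(_W[si], _W[sj]) + np.outer(_W[sj], _W[si]))
                    )
                    delta.append(_W[si] - _W[sj])
                    phase.append(off - off2)
        self.m_const = Mc
        self.pair_b = np.array(B) if B else np.zeros((0, 3, 3))
        self.pair_delta = np.array(delta) if delta else np.zeros((0, 3))
        self.pair_phase = np.array(phase)
        self.grav_coef = np.array(grav_coef)
        self.grav_rows = np.array(grav_row)
        self.grav_si = np.array([s for s, _ in grav_off])
        self.grav_off = np.array([o for _, o in grav_off])

    def inertia(self, q: np.ndarray) -> np.ndarray:
        ang = self.pair_delta @ q + self.pair_phase
        return self.m_const + np.einsum("p,pij->ij", np.cos(ang), self.pair_b)

    def dinertia(self, q: np.ndarray) -> np.ndarray:
        """dM[i] = dM/dq_i, analytic."""
        ang = self.pair_delta @ q + self.pair_phase
        return np.einsum(
            "p,pi,pjk->ijk", -np.sin(ang), self.pair_delta, self.pair_b
        )

    def com_height(self, q: np.ndarray) -> float:
        psi = (_W @ q)[self.grav_si] + self.grav_off
        return float(np.sum(self.grav_coef * -np.cos(psi)))

    def grav(self, q: np.ndarray, gravity: float) -> np.ndarray:
        psi = (_W @ q)[self.grav_si] + self.grav_off
        return gravity * (self.grav_coef * np.sin(psi)) @ self.grav_rows


_CHAIN_CACHE: dict[tuple, _Chain] = {}


def _chain(segs: SegmentParams) -> _Chain:
    key = tuple(
        v
        for s in (segs.thigh, segs.shank, segs.foot)
        for v in (s.mass, *s.com, s.inertia, s.length)
    )
    chain = _CHAIN_CACHE.get(key)
    if chain is None:
        chain = _CHAIN_CACHE[key] = _Chain(segs)
    return chain


def inertia_matrix(q: np.ndarray, segs: SegmentParams) -> np.ndarray:
    """Symmetric positive definite 3x3 inertia matrix M(q)."""
    return _chain(segs).inertia(np.asarray(q, dtype=float))


def coriolis_matrix(
    q: np.ndarray,
    qdot: np.ndarray,
    segs: SegmentParams,
    fd_step: float | None = None,
) -> np.ndarray:
    """Centrifugal/Coriolis matrix D(q, q̇) from Christoffel symbols.

    D_kj = 1/2 sum_i (dm_kj/dq_i + dm_ki/dq_j - dm_ij/dq_k) q̇_i, which makes
    (Ṁ - 2D) skew-symmetric.  The partials of M are analytic by default
    (M is a short cosine sum in q); passing ``fd_step`` switches to central
    finite differences of M, which serves as an independent cross-check.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    if fd_step is None:
        dM = _chain(segs).dinertia(q)
    else:
        dM = np.zeros((3, 3, 3))
        for i in range(3):
            dq = np.zeros(3)
            dq[i] = fd_step
            dM[i] = (
                inertia_matrix(q + dq, segs) - inertia_matrix(q - dq, segs)
            ) / (2.0 * fd_step)
    t1 = np.einsum("ikj,i->kj", dM, qdot)
    t2 = np.einsum("jki,i->kj", dM, qdot)
    t3 = np.einsum("kij,i->kj", dM, qdot)
    return 0.5 * (t1 + t2 - t3)


def potential_energy(
    q: np.ndarray, segs: SegmentParams, gravity: float = GRAVITY
) -> float:
    return gravity * _chain(segs).com_height(np.asarray(q, dtype=float))


def gravity_vector(
    q: np.ndarray, segs: SegmentParams, gravity: float = GRAVITY
) -> np.ndarray:
    """k(q) = dP/dq for the three segment masses (analytic)."""
    return _chain(segs).grav(np.asarray(q, dtype=float), gravity)


def kinetic_energy(q: np.ndarray, qdot: np.ndarray, segs: SegmentParams) -> float:
    qdot = np.asarray(qdot, dtype=float)
    return 0.5 * float(qdot @ inertia_matrix(q, segs) @ qdot)


def total_energy(
    q: np.ndarray, qdot: np.ndarray, segs: SegmentParams, gravity: float = GRAVITY
) -> float:
    return kinetic_energy(q, qdot, segs) + potential_energy(q, segs, gravity)


# ---------------------------------------------------------------------------
# joint torques
# ---------------------------------------------------------------------------

def viscous_torque(qdot_j: float, k_v: float, n_v: float) -> float:
    """Power-law viscous magnitude K sgn(q̇)|q̇|^n (odd in the rate).

    The value follows the printed form; the torque assembly subtracts it so
    the element dissipates energy.
    """
    if k_v < 0:
        raise ValueError("viscous gain must be non-negative")
    return k_v * math.copysign(abs(qdot_j) ** n_v, qdot_j) if qdot_j else 0.0


def elastic_torque_knee(
    q1: float, q2: float, q3: float, p: PassiveTorqueParams
) -> float:
    """Double-exponential knee elastic torque with an extension-limit term.

    Depends on hip and ankle angles through the biarticular muscle groups.
    """
    return (
        _safe_exp(p.a1k + p.b1k * q1 + p.c1k * q2 + p.d1k * q3)
        - _safe_exp(p.a2k + p.b2k * q1 + p.c2k * q2 + p.d2k * q3)
        + p.ek
        - _safe_exp(p.fk + p.gk * q2)
    )


def elastic_torque_ankle(q2: float, q3: float, p: PassiveTorqueParams) -> float:
    """Two-exponential ankle elastic torque; knee-dependent through GAS."""
    return (
        _safe_exp(p.a1a + p.b1a * q2 + p.c1a * q3)
        - _safe_exp(p.a2a + p.b2a * q2 + p.c2a * q3)
        + p.da
    )


def delastic_torque_ankle_dq3(
    q2: float, q3: float, p: PassiveTorqueParams
) -> float:
    """Analytic slope of the ankle elastic torque w.r.t. the ankle angle."""
    return p.c1a * _safe_exp(p.a1a + p.b1a * q2 + p.c1a * q3) - p.c2a * _safe_exp(
        p.a2a + p.b2a * q2 + p.c2a * q3
    )


def active_torque(
    lever_arms: np.ndarray, signs: np.ndarray, tendon_forces: np.ndarray
) -> float:
    """Signed sum of lever arm x tendon force over the muscles of one joint."""
    lever_arms = np.asarray(lever_arms, dtype=float)
    tendon_forces = np.asarray(tendon_forces, dtype=float)
    signs = np.asarray(signs, dtype=float)
    if not lever_arms.shape == signs.shape == tendon_forces.shape:
        raise ValueError("mismatched muscle ordering")
    return float(np.sum(signs * lever_arms * tendon_forces))


def grf_torque(
    joint_centre: np.ndarray, axis: np.ndarray, grf: GroundReaction
) -> float:
    """Scalar triple product ((p_GRF - o_j) x f_GRF) . e_zj."""
    axis = np.asarray(axis, dtype=float)
    if not math.isclose(np.linalg.norm(axis), 1.0, abs_tol=1e-9):
        raise ValueError("joint axis must be a unit vector")
    r = grf.p_grf - np.asarray(joint_centre, dtype=float)
    return float(np.cross(r, grf.f_grf) @ axis)


def reduced_dynamics(
    q_hat: np.ndarray,
    qdot_hat: np.ndarray,
    hip: tuple[float, float, float],
    tau_knee: float,
    tau_ankle: float,
    segs: SegmentParams,
    gravity: float = GRAVITY,
) -> np.ndarray:
    """Knee/ankle accelerations from the hip-reduced equations of motion.

    Solves M̂ q̂̈ = τ̂ - k̂ - D̂ q̂̇ where τ̂ folds the hip kinematics into the
    coupling columns of M and D.
    """
    q1, q1dot, q1ddot = hip
    q = np.array([q1, q_hat[0], q_hat[1]])
    qdot = np.array([q1dot, qdot_hat[0], qdot_hat[1]])
    M = inertia_matrix(q, segs)
    D = coriolis_matrix(q, qdot, segs)
    k = gravity_vector(q, segs, gravity)
    tau_hat = (
        np.array([tau_knee, tau_ankle])
        - q1ddot * M[1:, 0]
        - q1dot * D[1:, 0]
    )
    M_hat = M[1:, 1:]
    D_hat = D[1:, 1:]
    rhs = tau_hat - k[1:] - D_hat @ np.asarray(qdot_hat, dtype=float)
    try:
        return np.linalg.solve(M_hat, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by SPD
        raise np.linalg.LinAlgError("singular reduced inertia matrix") from exc


def discretise_step(
    x: np.ndarray, xdot: np.ndarray, t_s: float
) -> np.ndarray:
    """Explicit-Euler discretisation x_{k+1} = x_k + T_s f(x_k, u_k)."""
    if t_s <= 0:
        raise ValueError("sampling time must be positive")
    return np.asarray(x, dtype=float) + t_s * np.asarray(xdot, dtype=float)


# ---------------------------------------------------------------------------
# assembled plant model
# ---------------------------------------------------------------------------

class LowerExtremityModel:
    """EMG-driven knee/ankle plant: geometry tables + muscles + rigid bodies.

    Muscle ordering everywhere follows the state layout: RF, HAMS, VM, GAS,
    SOL, TA.
    """

    def __init__(
        self,
        geometry: kin.LowerLimbGeometry | None = None,
        tables: dict[str, kin.MuscleGeometryTable] | None = None,
        muscles: dict[str, mus.MuscleParams] | None = None,
        segments: SegmentParams | None = None,
        passive: PassiveTorqueParams | None = None,
        gravity: float = GRAVITY,
        tendon_ratio: float = 0.5,
        norm_length_neutral: float = 0.85,
    ) -> None:
        self.geometry = geometry or kin.LowerLimbGeometry()
        self.tables = tables or kin.build_geometry_tables(self.geometry)
        self.segments = segments or SegmentParams()
        self.passive = passive or PassiveTorqueParams()
        self.gravity = gravity
        self.muscles = muscles or mus.default_muscle_params()
        neutral = kin.JointConfiguration()
        for name in kin.MUSCLES:
            p = self.geometry.paths[name]
            mus.calibrate_lengths(
                self.muscles[name],
                self.geometry.mtc_length(name, neutral),
                p.pennation,
                tendon_ratio,
                norm_length_neutral,
            )
        self.knee_muscles = ("RF", "HAMS", "VM", "GAS")
        self.ankle_muscles = ("GAS", "SOL", "TA")

    # -- muscle layer -------------------------------------------------------

    def _muscle_kinematics(
        self, name: str, q: dict[str, float], rates: dict[str, float], clamp: bool
    ):
        table = self.tables[name]
        angles = {j: q[j] for j in table.joints}
        l_mt = table.length(clamp=clamp, **angles)
        v_m = table.contraction_velocity(rates, clamp=clamp, **angles)
        return table, angles, l_mt, v_m

    def tendon_forces(
        self,
        activations: np.ndarray,
        f_isom: np.ndarray,
        q: dict[str, float],
        rates: dict[str, float],
        clamp: bool = False,
    ) -> np.ndarray:
        forces = np.zeros(len(kin.MUSCLES))
        for i, name in enumerate(kin.MUSCLES):
            params = self.muscles[name]
            _t, _a, l_mt, v_m = self._muscle_kinematics(name, q, rates, clamp)
            l_m = params.fibre_length(l_mt)
            forces[i] = mus.tendon_force(
                None, activations[i], l_m, v_m, params, f_isom_bar=f_isom[i]
            )
        return forces

    def active_torques(
        self,
        activations: np.ndarray,
        f_isom: np.ndarray,
        q: dict[str, float],
        rates: dict[str, float],
        clamp: bool = False,
    ) -> tuple[float, float]:
        """Active knee and ankle torques (positive increases the angle)."""
        forces = self.tendon_forces(activations, f_isom, q, rates, clamp)
        tau = {"knee": 0.0, "ankle": 0.0}
        for joint, members in (
            ("knee", self.knee_muscles),
            ("ankle", self.ankle_muscles),
        ):
            r, s, f = [], [], []
            for name in members:
                table = self.tables[name]
                angles = {j: q[j] for j in table.joints}
                r.append(table.lever(joint, clamp=clamp, **angles))
                s.append(table.signs[joint])
                f.append(forces[kin.MUSCLES.index(name)])
            tau[joint] = active_torque(np.array(r), np.array(s), np.array(f))
        return tau["knee"], tau["ankle"]

    # -- full state derivative ---------------------------------------------

    def state_derivative(
        self,
        x: np.ndarray,
        u: np.ndarray,
        clamp: bool = False,
        grf: GroundReaction | None = None,
    ) -> np.ndarray:
        """Right-hand side of the 16-state model ẋ = f(x, u).

        ``clamp`` soft-clips joint angles to the geometry table ranges (used
        inside the filter, whose cubature points may transiently leave the
        admissible range) instead of raising.
        """
        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        if x.shape != (N_STATES,) or u.shape != (N_INPUTS,):
            raise ValueError("bad state or input dimension")
        s_emg = np.clip(u[:6], 0.0, 1.0)
        hip = (u[6], u[7], u[8])
        act = np.clip(x[IDX_ACT], 0.0, 1.0)
        f_isom = np.maximum(x[IDX_FORCE], 0.0)

        q = {"hip": hip[0], "knee": x[0], "ankle": x[1]}
        rates = {"hip": hip[1], "knee": x[2], "ankle": x[3]}

        tau_t_knee, tau_t_ankle = self.active_torques(
            act, f_isom, q, rates, clamp
        )
        p = self.passive
        tau_e_knee = elastic_torque_knee(q["hip"], q["knee"], q["ankle"], p)
        tau_e_ankle = elastic_torque_ankle(q["knee"], q["ankle"], p)
        # minus sign: the printed power law is a magnitude along sgn(qdot)
        tau_v_knee = -viscous_torque(x[2], p.k_v_knee, p.n_v_knee)
        tau_v_ankle = -viscous_torque(x[3], p.k_v_ankle, p.n_v_ankle)
        tau_ext_knee = tau_ext_ankle = 0.0
        if grf is None:
            grf = self.grf_from_input(u)
        if grf is not None and np.any(grf.f_grf):
            qc = kin.JointConfiguration(q["hip"], q["knee"], q["ankle"])
            axis = np.array([0.0, 0.0, 1.0])
            tau_ext_knee = grf_torque(
                self.geometry.joint_centre("knee", qc), axis, grf
            )
            tau_ext_ankle = grf_torque(
                self.geometry.joint_centre("ankle", qc), axis, grf
            )

        tau_knee = tau_t_knee + tau_e_knee + tau_v_knee + tau_ext_knee
        tau_ankle = tau_t_ankle + tau_e_ankle + tau_v_ankle + tau_ext_ankle

        qddot = reduced_dynamics(
            x[IDX_ANGLES],
            x[IDX_RATES],
            hip,
            tau_knee,
            tau_ankle,
            self.segments,
            self.gravity,
        )

        xdot = np.zeros(N_STATES)
        xdot[0] = x[2]
        xdot[1] = x[3]
        xdot[2:4] = qddot
        for i, name in enumerate(kin.MUSCLES):
            params = self.muscles[name]
            xdot[4 + i] = mus.activation_rate(act[i], s_emg[i], params)
            xdot[10 + i] = mus.contraction_rate(
                None, act[i], 0.0, 0.0, params, f_isom_bar=f_isom[i]
            )
        return xdot

    def grf_from_input(self, u: np.ndarray) -> GroundReaction | None:
        """Assemble the ground reaction from the CoP/GRF input channels."""
        u = np.asarray(u, dtype=float)
        if np.any(u[12:15]):
            return GroundReaction(u[9:12], u[12:15])
        return None

    def measurement_matrix(self) -> np.ndarray:
        return C_MEASURE.copy()
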