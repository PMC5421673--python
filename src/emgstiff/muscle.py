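"""Activation and Hill-type contraction dynamics for the six modelled muscles.

Each muscle carries two states: the activation ``a`` (first-order bilinear lag
from the normalised sEMG envelope, with a faster activation than deactivation
time constant) and the normalised isometric force ``F̄isom`` (first-order
activation-to-force development lag).  Tendon force is produced with a rigid
tendon, a Gaussian force-length factor evaluated at the current fibre length
and a hyperbolic (Hill) force-velocity factor, so the force depends
instantaneously on the musculotendon length and velocity.  Passive muscle
elasticity and viscosity are deliberately NOT part of the tendon force: they
are lumped into joint-level elastic/viscous torque elements in the dynamics
module, which avoids double counting.

The six muscles contribute 2 x 6 = 12 states to the plant model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class MuscleState:
    """Activation in [0, 1] and normalised isometric force >= 0."""

    a: float = 0.0
    f_isom_bar: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("activation must lie in [0, 1]")
        if self.f_isom_bar < 0.0:
            raise ValueError("normalised isometric force must be >= 0")


@dataclass
class MuscleParams:
    """Per-muscle dynamic parameters (defaults are non-canonical placeholders).

    ``f_max``          maximal isometric force, N
    ``l_opt``          optimal fibre length, m
    ``l_tendon``       constant (rigid) tendon length, m
    ``pennation``      pennation angle, rad
    ``tau_act``        activation time constant, s
    ``tau_deact``      deactivation time constant, s
    ``tau_force``      force development lag, s
    ``v_max``          maximal shortening velocity, m/s
    ``fl_width``       width of the Gaussian force-length curve (norm. length)
    ``fv_shape``       curvature of the shortening branch of force-velocity
    ``fv_ecc_max``     asymptotic eccentric force gain
    """

    f_max: float = 1000.0
    l_opt: float = 0.08
    l_tendon: float = 0.25
    pennation: float = 0.0
    tau_act: float = 0.015
    tau_deact: float = 0.06
    tau_force: float = 0.04
    v_max: float = 0.8
    fl_width: float = 0.35
    fv_shape: float = 0.25
    fv_ecc_max: float = 1.5

    def __post_init__(self) -> None:
        if min(self.tau_act, self.tau_deact, self.tau_force) <= 0.0:
            raise ValueError("time constants must be positive")
        if self.f_max <= 0.0:
            raise ValueError("maximal isometric force must be positive")

    def fibre_length(self, l_mt: float) -> float:
        """Fibre length under the rigid-tendon assumption."""
        return (l_mt - self.l_tendon) / math.cos(self.pennation)

    def force_length(self, l_m: float) -> float:
        """Gaussian active force-length factor, 1 at the optimal length."""
        x = (l_m / self.l_opt - 1.0) / self.fl_width
        return math.exp(-x * x)

    def force_velocity(self, v_m: float) -> float:
        """Hill force-velocity factor; v_m > 0 is lengthening.

        Hyperbolic shortening branch vanishing at -v_max, saturating
        eccentric branch approaching ``fv_ecc_max``; equals 1 at v_m = 0.
        """
        v = v_m / self.v_max
        k = self.fv_shape
        if v >= 0.0:
            return (self.fv_ecc_max * v + k) / (v + k)
        if v <= -1.0:
            return 0.0
        return (1.0 + v) / (1.0 - v / k)

    def dforce_velocity(self, v_m: float) -> float:
        """Derivative of the force-velocity factor w.r.t. v_m (1 per m/s)."""
        v = v_m / self.v_max
        k = self.fv_shape
        if v >= 0.0:
            d = (self.fv_ecc_max - 1.0) * k / (v + k) ** 2
        elif v <= -1.0:
            d = 0.0
        else:
            d = (1.0 + 1.0 / k) / (1.0 - v / k) ** 2
        return d / self.v_max

    def dforce_length(self, l_m: float) -> float:
        """Derivative of the force-length factor w.r.t. l_m (1/m)."""
        x = (l_m / self.l_opt - 1.0) / self.fl_width
        return -2.0 * x * math.exp(-x * x) / (self.fl_width * self.l_opt)


def activation_rate(a: float, s: float, params: MuscleParams) -> float:
    """Bilinear first-order activation dynamics da/dt.

    The effective rate constant blends 1/tau_act and 1/tau_deact with the
    excitation level, so activation is faster than deactivation; a -> s under
    constant excitation.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("sEMG envelope must lie in [0, 1]")
    c_deact = 1.0 / params.tau_deact
    c_act = 1.0 / params.tau_act - c_deact
    return (s - a) * (c_act * s + c_deact)


def contraction_rate(
    state: MuscleState | None,
    a: float,
    l_m: float,
    v_m: float,
    params: MuscleParams,
    f_isom_bar: float | None = None,
) -> float:
    """Rate of the normalised isometric force state.

    First-order force-development lag toward the current activation; at rest
    (a = 0, F̄ = 0) the rate is zero, and under constant activation with the
    fibre at its optimum the state converges to ``a``.
    """
    f_bar = state.f_isom_bar if f_isom_bar is None else f_isom_bar
    return (a - f_bar) / params.tau_force


def tendon_force(
    state: MuscleState | None,
    a: float,
    l_m: float,
    v_m: float,
    params: MuscleParams,
    f_isom_bar: float | None = None,
) -> float:
    """Active tendon force, N (non-negative).

    F_T = F_max * F̄isom * f_l(l_M) * f_v(v_M) with a rigid tendon; passive
    joint-level viscoelasticity is handled by the dynamics module.
    """
    f_bar = state.f_isom_bar if f_isom_bar is None else f_isom_bar
    f_bar = max(f_bar, 0.0)
    return (
        params.f_max
        * f_bar
        * params.force_length(l_m)
        * params.force_velocity(v_m)
    )


def default_muscle_params() -> dict[str, MuscleParams]:
    """Non-canonical maximal forces and time constants for the six muscles.

    Tendon and optimal fibre lengths are derived from the path geometry at
    assembly time (see :func:`calibrate_lengths`), so these defaults carry
    only the force- and time-scale information.
    """
    f_max = {
        "RF": 850.0,
        "HAMS": 1300.0,
        "VM": 1200.0,
        "GAS": 1500.0,
        "SOL": 2600.0,
        "TA": 600.0,
    }
    return {name: MuscleParams(f_max=f) for name, f in f_max.items()}


def calibrate_lengths(
    params: MuscleParams,
    l_mt_neutral: float,
    pennation: float,
    tendon_ratio: float = 0.5,
    norm_length_neutral: float = 0.85,
) -> MuscleParams:
    """Fix tendon and optimal fibre length from the neutral-posture MTC length.

    The rigid tendon takes ``tendon_ratio`` of the neutral MTC length and the
    optimal fibre length is set so the fibre sits at ``norm_length_neutral``
    (on the ascending limb of the force-length curve) in the neutral posture.
    """
    l_t = tendon_ratio * l_mt_neutral
    l_fibre = (l_mt_neutral - l_t) / math.cos(pennation)
    params.l_tendon = l_t
    params.l_opt = l_fibre / norm_length_neutral
    params.pennation = pennation
    params.v_max = 10.0 * params.l_opt
    return params
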