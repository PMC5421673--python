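"""Joint-torque reconstruction and ankle quasi-stiffness from filter states.

Quasi-stiffness is the derivative of the joint torque with respect to the
joint angle.  For the EMG-driven model the active ankle torque is
tau = sum_i sgn_i r_i F_i, so by the product rule

    d tau / d phi = sum_i sgn_i (dr_i/dphi F_i + r_i dF_i/dphi),

with the lever-arm derivative taken analytically from the quartic geometry
tables and the tendon-force derivative taken at frozen muscle states
(activation and normalised isometric force held): stiffness is an
instantaneous mechanical property, so only the force-length and
force-velocity factors respond to the virtual angle change.

Sign convention: internally torques are positive in the direction of
increasing (dorsiflexion-positive) ankle angle; the reported ankle torque and
stiffness use the clinical plantarflexion-positive convention, which makes
the quasi-stiffness of a restoring joint positive and monotonically
increasing under antagonist coactivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import dynamics as dyn
from . import kinematics as kin
from . import muscle as mus


def _frozen_ankle_torque(
    model: dyn.LowerExtremityModel,
    phi_ankle: float,
    q: dict[str, float],
    rates: dict[str, float],
    act: np.ndarray,
    f_isom: np.ndarray,
) -> float:
    """Active ankle torque at a perturbed ankle angle, muscle states frozen.

    Internal (dorsiflexion-positive) convention; geometry queries clamp so
    the perturbation remains evaluable at the range edges.
    """
    q_mod = dict(q)
    q_mod["ankle"] = phi_ankle
    tau = 0.0
    for name in model.ankle_muscles:
        table = model.tables[name]
        params = model.muscles[name]
        angles = {j: q_mod[j] for j in table.joints}
        l_mt = table.length(clamp=True, **angles)
        v_m = table.contraction_velocity(rates, clamp=True, **angles)
        i = kin.MUSCLES.index(name)
        f_t = mus.tendon_force(
            None, act[i], params.fibre_length(l_mt), v_m, params,
            f_isom_bar=f_isom[i],
        )
        tau += table.signs["ankle"] * table.lever("ankle", clamp=True, **angles) * f_t
    return tau


def reconstruct_torque(
    model: dyn.LowerExtremityModel, x_hat: np.ndarray, u: np.ndarray
) -> dict[str, float]:
    """Active knee/ankle torques evaluated at an estimated state.

    ``tau_ankle_plantar`` is the same ankle torque in the clinical
    plantarflexion-positive convention used for stiffness reporting.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    u = np.asarray(u, dtype=float)
    q = {"hip": u[6], "knee": x_hat[0], "ankle": x_hat[1]}
    rates = {"hip": u[7], "knee": x_hat[2], "ankle": x_hat[3]}
    act = np.clip(x_hat[dyn.IDX_ACT], 0.0, 1.0)
    f_isom = np.maximum(x_hat[dyn.IDX_FORCE], 0.0)
    tau_knee, tau_ankle = model.active_torques(act, f_isom, q, rates, clamp=True)
    return {
        "tau_knee": tau_knee,
        "tau_ankle": tau_ankle,
        "tau_ankle_plantar": -tau_ankle,
    }


def quasi_stiffness(
    model: dyn.LowerExtremityModel, x_hat: np.ndarray, u: np.ndarray
) -> dict[str, float]:
    """Analytic ankle quasi-stiffness at an estimated state (N m/rad).

    Returns the active muscle term (product rule over lever arms and tendon
    forces, muscle states frozen), the passive elastic term (slope of the
    ankle elastic torque) and their sum, all in the plantarflexion-positive
    torque convention (positive = restoring).
    """
    x_hat = np.asarray(x_hat, dtype=float)
    u = np.asarray(u, dtype=float)
    q = {"hip": u[6], "knee": x_hat[0], "ankle": x_hat[1]}
    rates = {"hip": u[7], "knee": x_hat[2], "ankle": x_hat[3]}
    act = np.clip(x_hat[dyn.IDX_ACT], 0.0, 1.0)
    f_isom = np.maximum(x_hat[dyn.IDX_FORCE], 0.0)

    dtau = 0.0  # internal convention: d tau_ankle / d phi_ankle
    for name in model.ankle_muscles:
        table = model.tables[name]
        params = model.muscles[name]
        angles = {j: q[j] for j in table.joints}
        sgn = table.signs["ankle"]
        r = table.lever("ankle", clamp=True, **angles)
        dr = table.dlever("ankle", clamp=True, **angles)
        l_mt = table.length(clamp=True, **angles)
        dl = table.dlength("ankle", clamp=True, **angles)
        v_m = table.contraction_velocity(rates, clamp=True, **angles)
        cos_p = math.cos(params.pennation)
        l_m = params.fibre_length(l_mt)
        i = kin.MUSCLES.index(name)
        f_bar = f_isom[i]
        f_l = params.force_length(l_m)
        f_v = params.force_velocity(v_m)
        f_t = params.f_max * f_bar * f_l * f_v
        # dF/dphi at frozen states: through f_l (fibre length) and f_v
        # (contraction velocity depends on the length partials, which vary
        # with the angle)
        dv = sum(
            rates.get(j, 0.0)
            * (
                table.d2length("ankle", clamp=True, **angles)
                if j == "ankle"
                else table.dlength_mixed(j, "ankle", clamp=True, **angles)
            )
            for j in table.joints
        ) / cos_p
        df = params.f_max * f_bar * (
            params.dforce_length(l_m) * (dl / cos_p) * f_v
            + f_l * params.dforce_velocity(v_m) * dv
        )
        dtau += sgn * (dr * f_t + r * df)

    kappa_active = -dtau  # plantarflexion-positive reporting convention
    kappa_passive = -dyn.delastic_torque_ankle_dq3(q["knee"], q["ankle"], model.passive)
    return {
        "kappa_active": kappa_active,
        "kappa_passive": kappa_passive,
        "kappa_total": kappa_active + kappa_passive,
    }


def quasi_stiffness_fd(
    model: dyn.LowerExtremityModel,
    x_hat: np.ndarray,
    u: np.ndarray,
    step: float = 1e-4,
) -> float:
    """Finite-difference active quasi-stiffness (frozen muscle states).

    Central difference of the reconstructed ankle torque over the ankle
    angle; serves as the numerical cross-check of :func:`quasi_stiffness`.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    u = np.asarray(u, dtype=float)
    q = {"hip": u[6], "knee": x_hat[0], "ankle": x_hat[1]}
    rates = {"hip": u[7], "knee": x_hat[2], "ankle": x_hat[3]}
    act = np.clip(x_hat[dyn.IDX_ACT], 0.0, 1.0)
    f_isom = np.maximum(x_hat[dyn.IDX_FORCE], 0.0)
    hi = _frozen_ankle_torque(model, q["ankle"] + step, q, rates, act, f_isom)
    lo = _frozen_ankle_torque(model, q["ankle"] - step, q, rates, act, f_isom)
    return -(hi - lo) / (2.0 * step)


@dataclass
class StiffnessSeries:
    """Time-resolved ankle quasi-stiffness with its companion torque."""

    time: np.ndarray
    kappa_active: np.ndarray
    kappa_passive: np.ndarray
    tau_ankle: np.ndarray  # plantarflexion-positive
    smoothing_window: int = 1

    @property
    def kappa_total(self) -> np.ndarray:
        return self.kappa_active + self.kappa_passive


def stiffness_series(
    model: dyn.LowerExtremityModel,
    time: np.ndarray,
    estimates: np.ndarray,
    inputs: np.ndarray,
) -> StiffnessSeries:
    """Evaluate torque and quasi-stiffness along a filtered state trajectory."""
    n = len(time)
    ka = np.zeros(n)
    kp = np.zeros(n)
    tau = np.zeros(n)
    for k in range(n):
        s = quasi_stiffness(model, estimates[k], inputs[k])
        ka[k] = s["kappa_active"]
        kp[k] = s["kappa_passive"]
        tau[k] = reconstruct_torque(model, estimates[k], inputs[k])[
            "tau_ankle_plantar"
        ]
    return StiffnessSeries(np.asarray(time, float), ka, kp, tau)


def smooth_stiffness(series: StiffnessSeries, window: int = 51) -> StiffnessSeries:
    """Moving-average smoothing of the stiffness channels.

    The raw series keeps short-lived peaks (which can reach unphysiological
    values when noisy envelopes hit the contraction dynamics); the smoothed
    variant is the one to compare against published average stiffness values.
    A window of one sample is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return series

    def avg(x: np.ndarray) -> np.ndarray:
        kernel = np.ones(window) / window
        pad = window // 2
        xp = np.pad(x, pad, mode="edge")
        return np.convolve(xp, kernel, mode="valid")[: x.size]

    return StiffnessSeries(
        series.time,
        avg(series.kappa_active),
        avg(series.kappa_passive),
        avg(series.tau_ankle),
        smoothing_window=window,
    )


def coactivation_stiffness(
    model: dyn.LowerExtremityModel,
    scale: float,
    q: dict[str, float] | None = None,
) -> dict[str, float]:
    """Quasi-stiffness at a held posture under scaled antagonist coactivation.

    Dorsiflexor (TA) and plantar flexors (SOL, GAS) are activated together in
    a fixed ratio multiplied by ``scale``; muscle force states are set to
    their activation equilibrium.  Raising the scale should raise the ankle
    stiffness while changing the net torque comparatively little — the
    coactivation mechanism the estimator is built to expose.
    """
    if not 0.0 <= scale <= 1.0:
        raise ValueError("coactivation scale must lie in [0, 1]")
    q = q or {"hip": 0.0, "knee": 0.2, "ankle": -0.1}
    ratios = {"TA": 0.4, "SOL": 0.13, "GAS": 0.07}
    x = np.zeros(dyn.N_STATES)
    x[0], x[1] = q["knee"], q["ankle"]
    for name, ratio in ratios.items():
        i = kin.MUSCLES.index(name)
        x[4 + i] = ratio * scale
        x[10 + i] = ratio * scale  # force state at its activation fixed point
    u = np.zeros(dyn.N_INPUTS)
    u[6] = q["hip"]
    s = quasi_stiffness(model, x, u)
    s["tau_ankle_plantar"] = reconstruct_torque(model, x, u)["tau_ankle_plantar"]
    return s
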