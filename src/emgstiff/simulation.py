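"""Forward simulation of the in-silico validation protocol.

The protocol emulates the dynamic estimator test: the hip swings sinusoidally
(default 20 deg amplitude at pi/2 rad/s), the six muscles are activated in
5 s blocks separated by 5 s rest (each muscle group in turn, one antagonist
coactivation block and one knee block), all joints start at zero, and white
Gaussian noise is added both to the plant states and to the joint-angle
measurements.  Ground truth is integrated with fixed-step 4th-order
Runge-Kutta at ten times the estimator rate, so the estimator's explicit
Euler model sees a genuine discretisation mismatch; the estimator itself
(:class:`~emgstiff.sckf.SquareRootCKF`) runs at the default 100 Hz.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import kinematics as kin
from . import sckf
from .signals import EnvelopeSeries, hip_kinematics


@dataclass
class ActivationBlock:
    """One on-block of a muscle's activation schedule."""

    muscle: str
    start: float
    stop: float
    level: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("activation level must lie in [0, 1]")
        if self.stop <= self.start:
            raise ValueError("block must have positive duration")


def default_blocks() -> list[ActivationBlock]:
    """Each ankle muscle group in turn, an antagonist coactivation phase and
    a knee phase, in 5 s on / 5 s rest alternation."""
    B = ActivationBlock
    return [
        B("TA", 0.0, 5.0, 0.25),
        B("SOL", 10.0, 15.0, 0.20),
        B("GAS", 10.0, 15.0, 0.12),
        # antagonist coactivation: raises ankle stiffness at little net torque
        B("TA", 20.0, 25.0, 0.25),
        B("SOL", 20.0, 25.0, 0.15),
        B("GAS", 20.0, 25.0, 0.08),
        # knee flexor/extensor phase (flexor-dominant: the extensors would
        # otherwise drive the knee into the extension stop)
        B("RF", 25.0, 30.0, 0.10),
        B("VM", 25.0, 30.0, 0.06),
        B("HAMS", 25.0, 30.0, 0.20),
    ]


@dataclass
class NoiseScales:
    """Per-block additive noise standard deviations (per estimator step)."""

    angle: float = 2e-4      # rad
    rate: float = 2e-3       # rad/s
    activation: float = 1e-3
    force: float = 1e-3
    measurement: float = math.radians(0.3)  # rad, joint-angle sensors

    def state_std(self) -> np.ndarray:
        out = np.empty(dyn.N_STATES)
        out[0:2] = self.angle
        out[2:4] = self.rate
        out[4:10] = self.activation
        out[10:16] = self.force
        return out


@dataclass
class Protocol:
    """In-silico experiment description (the shipped defaults ARE the study
    conditions: hip 20 deg sinusoid at pi/2 rad/s, 5 s activation blocks,
    zero initial angles, modest state/measurement noise)."""

    duration: float = 30.0
    fs: float = 100.0
    hip_amplitude_deg: float = 20.0
    hip_omega: float = math.pi / 2.0
    blocks: list[ActivationBlock] = field(default_factory=default_blocks)
    rise_time: float = 0.15
    emg_noise: float = 0.0
    noise: NoiseScales = field(default_factory=NoiseScales)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * self.fs))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def synth_emg(
    protocol: Protocol, rng: np.random.Generator | None = None
) -> EnvelopeSeries:
    """Block-wise activation envelopes with smooth rise/fall transients."""
    t = np.arange(protocol.n_steps) / protocol.fs
    rise = max(protocol.rise_time, 1e-9)
    values = {m: np.zeros_like(t) for m in kin.MUSCLES}
    for b in protocol.blocks:
        env = b.level * (
            _smoothstep((t - b.start) / rise) - _smoothstep((t - b.stop) / rise)
        )
        values[b.muscle] = values[b.muscle] + env
    if protocol.emg_noise > 0.0:
        rng = rng or np.random.default_rng(protocol.seed)
        for m in kin.MUSCLES:
            values[m] = values[m] * (
                1.0 + protocol.emg_noise * rng.standard_normal(t.size)
            )
    for m in kin.MUSCLES:
        values[m] = np.clip(values[m], 0.0, 1.0)
    return EnvelopeSeries(time=t, values=values)


def build_inputs(protocol: Protocol, rng: np.random.Generator | None = None):
    """Input matrix u(t) (n_steps x 15) on the estimator time base.

    Hip velocity and acceleration are produced from the hip angle with the
    band-limited differentiation filter, as in the on-line pipeline; CoP and
    GRF channels are zero (free-swinging leg, no ground contact).
    """
    t = np.arange(protocol.n_steps) / protocol.fs
    emg = synth_emg(protocol, rng)
    hip = math.radians(protocol.hip_amplitude_deg) * np.sin(protocol.hip_omega * t)
    hip_rate, hip_accel = hip_kinematics(hip, 1.0 / protocol.fs)
    u = np.zeros((protocol.n_steps, dyn.N_INPUTS))
    for i, m in enumerate(kin.MUSCLES):
        u[:, i] = emg.values[m]
    u[:, 6] = hip
    u[:, 7] = hip_rate
    u[:, 8] = hip_accel
    return t, u


@dataclass
class SimulationRecord:
    """Truth states, inputs, noisy measurements and torques of one run."""

    time: np.ndarray
    states: np.ndarray        # (N, 16) truth
    inputs: np.ndarray        # (N, 15)
    measurements: np.ndarray  # (N, 2) noisy angles
    torques: np.ndarray       # (N, 4): active knee/ankle, total knee/ankle
    metadata: dict

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.time, self.states, self.inputs, self.measurements,
                    self.torques):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        state_cols = STATE_NAMES
        input_cols = INPUT_NAMES
        pd.DataFrame(
            np.column_stack([self.time, self.states]),
            columns=["time", *state_cols],
        ).to_csv(directory / "states.csv", index=False)
        pd.DataFrame(
            np.column_stack([self.time, self.inputs]),
            columns=["time", *input_cols],
        ).to_csv(directory / "inputs.csv", index=False)
        pd.DataFrame(
            np.column_stack([self.time, self.measurements]),
            columns=["time", "phi_knee_meas", "phi_ankle_meas"],
        ).to_csv(directory / "measurements.csv", index=False)
        pd.DataFrame(
            np.column_stack([self.time, self.torques]),
            columns=["time", *TORQUE_NAMES],
        ).to_csv(directory / "torques.csv", index=False)
        (directory / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, default=str)
        )


STATE_NAMES = [
    "phi_knee", "phi_ankle", "dphi_knee", "dphi_ankle",
    *[f"a_{m}" for m in kin.MUSCLES],
    *[f"fisom_{m}" for m in kin.MUSCLES],
]
INPUT_NAMES = [
    *[f"s_{m}" for m in kin.MUSCLES],
    "phi_hip", "dphi_hip", "ddphi_hip",
    "cop_x", "cop_y", "cop_z", "grf_x", "grf_y", "grf_z",
]
TORQUE_NAMES = ["tau_act_knee", "tau_act_ankle", "tau_tot_knee", "tau_tot_ankle"]


def _rk4_step(f, x, h):
    k1 = f(x)
    k2 = f(x + 0.5 * h * k1)
    k3 = f(x + 0.5 * h * k2)
    k4 = f(x + h * k3)
    return x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def joint_torques(
    model: dyn.LowerExtremityModel, x: np.ndarray, u: np.ndarray
) -> tuple[float, float, float, float]:
    """Active and total knee/ankle torques at a given state and input."""
    q = {"hip": u[6], "knee": x[0], "ankle": x[1]}
    rates = {"hip": u[7], "knee": x[2], "ankle": x[3]}
    act = np.clip(x[dyn.IDX_ACT], 0.0, 1.0)
    f_isom = np.maximum(x[dyn.IDX_FORCE], 0.0)
    ta_k, ta_a = model.active_torques(act, f_isom, q, rates, clamp=True)
    p = model.passive
    tot_k = (
        ta_k
        + dyn.elastic_torque_knee(q["hip"], q["knee"], q["ankle"], p)
        - dyn.viscous_torque(x[2], p.k_v_knee, p.n_v_knee)
    )
    tot_a = (
        ta_a
        + dyn.elastic_torque_ankle(q["knee"], q["ankle"], p)
        - dyn.viscous_torque(x[3], p.k_v_ankle, p.n_v_ankle)
    )
    return ta_k, ta_a, tot_k, tot_a


def forward_simulate(
    protocol: Protocol,
    model: dyn.LowerExtremityModel | None = None,
    substeps: int = 10,
    rng: np.random.Generator | None = None,
    x0: np.ndarray | None = None,
    integrator: str = "rk4",
) -> SimulationRecord:
    """Integrate the truth model over the protocol and emit noisy data.

    Truth uses fixed-step RK4 at ``substeps`` times the estimator rate with
    the inputs held over each substep, so the estimator's Euler model sees a
    genuine discretisation mismatch; state noise is injected once per
    estimator step, measurement noise on the recorded joint angles.
    ``integrator="euler"`` (with ``substeps=1``) reproduces the estimator's
    transition exactly, which is useful for perfect-model checks.
    """
    model = model or dyn.LowerExtremityModel()
    rng = rng or np.random.default_rng(protocol.seed)
    t, u = build_inputs(protocol, rng)
    n = protocol.n_steps
    ts = 1.0 / protocol.fs
    h = ts / substeps
    x = np.zeros(dyn.N_STATES) if x0 is None else np.asarray(x0, float).copy()
    states = np.zeros((n, dyn.N_STATES))
    torques = np.zeros((n, 4))
    state_std = protocol.noise.state_std()
    for k in range(n):
        states[k] = x
        torques[k] = joint_torques(model, x, u[k])
        uk = u[k]
        f = lambda xx: model.state_derivative(xx, uk, clamp=True)
        for _ in range(substeps):
            if integrator == "euler":
                x = dyn.discretise_step(x, f(x), h)
            else:
                x = _rk4_step(f, x, h)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"truth integration diverged at t = {t[k]:.3f} s"
                )
        x = x + state_std * rng.standard_normal(dyn.N_STATES)
        x[dyn.IDX_ACT] = np.clip(x[dyn.IDX_ACT], 0.0, 1.0)
        x[dyn.IDX_FORCE] = np.maximum(x[dyn.IDX_FORCE], 0.0)
    meas = states[:, :2] + protocol.noise.measurement * rng.standard_normal((n, 2))
    metadata = {
        "protocol": asdict(protocol),
        "substeps": substeps,
        "state_layout": STATE_NAMES,
        "input_layout": INPUT_NAMES,
    }
    return SimulationRecord(t, states, u, meas, torques, metadata)


@dataclass
class FilterConfig:
    """SCKF configuration: step size, noise factors and initial covariance."""

    ts: float = 0.01
    sq_angle: float = 5e-4
    sq_rate: float = 5e-3
    sq_activation: float = 3e-3
    sq_force: float = 3e-3
    sr_angle: float = math.radians(0.3)
    s0_angle: float = 0.01
    s0_rate: float = 0.1
    s0_muscle: float = 0.05
    clamp_states: bool = True

    def noise_factors(self) -> sckf.NoiseFactors:
        sq = np.empty(dyn.N_STATES)
        sq[0:2] = self.sq_angle
        sq[2:4] = self.sq_rate
        sq[4:10] = self.sq_activation
        sq[10:16] = self.sq_force
        return sckf.NoiseFactors(np.diag(sq), np.eye(2) * self.sr_angle)

    def initial_sqrt(self) -> np.ndarray:
        s0 = np.empty(dyn.N_STATES)
        s0[0:2] = self.s0_angle
        s0[2:4] = self.s0_rate
        s0[4:16] = self.s0_muscle
        return np.diag(s0)


def _state_constraint(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[dyn.IDX_ACT] = np.clip(out[dyn.IDX_ACT], 0.0, 1.0)
    out[dyn.IDX_FORCE] = np.clip(out[dyn.IDX_FORCE], 0.0, 1.5)
    return out


def run_filter(
    record: SimulationRecord,
    model: dyn.LowerExtremityModel,
    config: FilterConfig | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, sckf.SquareRootCKF]:
    """Run the SCKF over a recorded (or measured) data set.

    The filter's transition is the explicit-Euler discretisation of the
    plant model with table clamping enabled, per the estimator design.
    """
    config = config or FilterConfig()
    ts = config.ts

    def f_d(x, u):
        return dyn.discretise_step(x, model.state_derivative(x, u, clamp=True), ts)

    ckf = sckf.SquareRootCKF(
        f_d=f_d,
        h_d=model.measurement_matrix(),
        noise=config.noise_factors(),
        x0=np.zeros(dyn.N_STATES) if x0 is None else x0,
        s0=config.initial_sqrt(),
        constrain=_state_constraint if config.clamp_states else None,
    )
    estimates = np.zeros_like(record.states)
    # sample k is reached by propagating with the input held over step k-1,
    # then corrected with the measurement taken at k
    estimates[0] = ckf.correct(record.measurements[0]).x_hat
    for k in range(1, record.time.size):
        state = ckf.step(record.measurements[k], record.inputs[k - 1])
        estimates[k] = state.x_hat
    return estimates, ckf


def _rms(x: np.ndarray, axis=0) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def run_estimation_experiment(
    protocol: Protocol | None = None,
    model: dyn.LowerExtremityModel | None = None,
    filter_config: FilterConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Forward-simulate the protocol, run the SCKF and report RMS errors.

    Returns a machine-readable report with per-channel RMS errors of the
    joint angles (deg), angular rates (rad/s) and reconstructed torques
    (N m), plus the raw series for downstream analysis.
    """
    protocol = protocol or Protocol()
    if seed is not None:
        protocol.seed = seed
    model = model or dyn.LowerExtremityModel()
    filter_config = filter_config or FilterConfig(ts=1.0 / protocol.fs)
    rng = np.random.default_rng(protocol.seed)
    record = forward_simulate(protocol, model, rng=rng)
    estimates, ckf = run_filter(record, model, filter_config)

    err = estimates - record.states
    angle_rms_deg = np.degrees(_rms(err[:, 0:2]))
    rate_rms = _rms(err[:, 2:4])
    est_torques = np.array(
        [
            joint_torques(model, estimates[k], record.inputs[k])
            for k in range(record.time.size)
        ]
    )
    torque_rms = _rms(est_torques - record.torques)
    report = {
        "n_steps": int(record.time.size),
        "rms_angle_deg": {
            "knee": float(angle_rms_deg[0]),
            "ankle": float(angle_rms_deg[1]),
        },
        "rms_rate_rad_s": {
            "knee": float(rate_rms[0]),
            "ankle": float(rate_rms[1]),
        },
        "rms_torque_nm": {name: float(v) for name, v in zip(TORQUE_NAMES, torque_rms)},
        "constraint_events": ckf.constraint_events,
        "seed": protocol.seed,
    }
    return {
        "report": report,
        "record": record,
        "estimates": estimates,
        "estimated_torques": est_torques,
    }
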