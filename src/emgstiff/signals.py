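"""sEMG envelope extraction and band-limited differentiation of hip angles.

Raw sEMG is band-pass filtered (10-500 Hz at a 1500 Hz sampling rate),
rectified, low-pass filtered to a linear envelope, normalised to the maximum
voluntary contraction (MVC) and clipped to [0, 1], then resampled to the
common estimator rate (default 100 Hz, the orientation-sensor rate).

Hip angular velocity and acceleration are produced from the hip angle with a
band-limited differentiator G(s) = s / ((s/30 + 1)(s/300 + 1)^2): an ideal
differentiator below ~30 rad/s whose poles bound the high-frequency noise
gain; applying it twice yields the second derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class EnvelopeConfig:
    """Filter corners (Hz) and rates for envelope extraction."""

    fs_raw: float = 1500.0
    fs_out: float = 100.0
    highpass_hz: float = 10.0
    lowpass_hz: float = 500.0
    envelope_hz: float = 6.0
    order: int = 4
    zero_phase: bool = False  # causal by default: the estimator is on-line


@dataclass
class EnvelopeSeries:
    """Uniformly sampled per-muscle envelopes in [0, 1]."""

    time: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.time.shape:
                raise ValueError(f"{name}: envelope/time length mismatch")
            self.values[name] = v


def emg_envelope(
    raw: np.ndarray,
    mvc_value: float,
    config: EnvelopeConfig | None = None,
) -> np.ndarray:
    """Band-pass, rectify, low-pass, MVC-normalise and resample one channel."""
    config = config or EnvelopeConfig()
    if mvc_value <= 0:
        raise ValueError("MVC value must be positive")
    raw = np.asarray(raw, dtype=float)
    nyq = 0.5 * config.fs_raw
    if raw.size < 12 * config.order:
        raise ValueError("input too short for filter warm-up")
    hi = min(config.lowpass_hz, 0.99 * nyq)
    sos_band = sps.butter(
        config.order, [config.highpass_hz / nyq, hi / nyq], btype="band", output="sos"
    )
    x = (sps.sosfiltfilt if config.zero_phase else sps.sosfilt)(sos_band, raw)
    x = np.abs(x)
    sos_env = sps.butter(config.order, config.envelope_hz / nyq, output="sos")
    x = (sps.sosfiltfilt if config.zero_phase else sps.sosfilt)(sos_env, x)
    x = np.clip(x / mvc_value, 0.0, 1.0)
    up, down = _resample_ratio(config.fs_out, config.fs_raw)
    # the polyphase FIR can ring slightly past the clip bounds
    return np.clip(sps.resample_poly(x, up, down), 0.0, 1.0)


def _resample_ratio(fs_out: float, fs_in: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return frac.numerator, frac.denominator


def differentiator_tf(fc1: float = 30.0, fc2: float = 300.0):
    """Continuous-time transfer function s / ((s/fc1 + 1)(s/fc2 + 1)^2)."""
    num = [1.0, 0.0]
    den = np.polymul([1.0 / fc1, 1.0], np.polymul([1.0 / fc2, 1.0], [1.0 / fc2, 1.0]))
    return num, den


def differentiate_filtered(
    x: np.ndarray,
    t_s: float,
    fc1: float = 30.0,
    fc2: float = 300.0,
) -> np.ndarray:
    """Band-limited derivative via the bilinear-discretised differentiator."""
    num, den = differentiator_tf(fc1, fc2)
    bz, az = sps.bilinear(num, den, fs=1.0 / t_s)
    return sps.lfilter(bz, az, np.asarray(x, dtype=float))


def hip_kinematics(
    phi_hip: np.ndarray, t_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Hip angular velocity and acceleration from the hip angle trajectory.

    The differentiation filter is applied once for the rate and twice for the
    acceleration, matching the on-line processing of the estimator inputs.
    """
    rate = differentiate_filtered(phi_hip, t_s)
    accel = differentiate_filtered(rate, t_s)
    return rate, accel
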