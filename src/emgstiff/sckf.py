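"""Generic third-degree square-root cubature Kalman filter (SCKF).

For an additive-noise discrete model x_{k+1} = f_d(x_k, u_k) + n_k,
y_k = h_d(x_k) + m_k, the CKF approximates the Gaussian-weighted integrals of
the Bayesian recursion with a third-degree spherical-radial cubature rule:
2n points at +-sqrt(n) along the coordinate axes, all with weight 1/(2n) —
no negatively weighted sampling points, which is what makes the square-root
formulation well conditioned.  The covariance is propagated exclusively as a
lower-triangular factor S with P = S S^T, updated by QR triangularisation,
and the Kalman gain is obtained by two triangular solves (never an explicit
inverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import qr, solve_triangular


class SingularInnovationError(np.linalg.LinAlgError):
    """The innovation square-root factor is (numerically) rank deficient."""


@dataclass
class CubatureRule:
    """Cubature points (rows) and uniform weights of the third-degree rule."""

    points: np.ndarray
    weights: np.ndarray


def cubature_points(n: int) -> CubatureRule:
    """2n points +-sqrt(n) e_i with equal weights 1/(2n)."""
    if n < 1:
        raise ValueError("state dimension must be >= 1")
    eye = np.eye(n)
    pts = np.sqrt(n) * np.vstack([eye, -eye])
    w = np.full(2 * n, 1.0 / (2 * n))
    return CubatureRule(points=pts, weights=w)


def triangularise(a: np.ndarray) -> np.ndarray:
    """tria(A): lower-triangular S with S S^T = A A^T, non-negative diagonal.

    Implemented with a QR decomposition of A^T; the diagonal sign is
    normalised so results are deterministic across platforms.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    n, m = a.shape
    if m < n:
        raise ValueError("tria() needs at least as many columns as rows")
    r = qr(a.T, mode="economic")[1]
    s = r.T
    signs = np.sign(np.diag(s))
    signs[signs == 0] = 1.0
    return s * signs[np.newaxis, :]


@dataclass
class SqrtFilterState:
    """Mean estimate and lower-triangular covariance square root."""

    x_hat: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.x_hat = np.asarray(self.x_hat, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = self.x_hat.size
        if self.s.shape != (n, n):
            raise ValueError("square-root factor shape mismatch")

    @property
    def covariance(self) -> np.ndarray:
        return self.s @ self.s.T


@dataclass
class NoiseFactors:
    """Square-root factors of process and measurement noise covariances."""

    s_q: np.ndarray
    s_r: np.ndarray

    def __post_init__(self) -> None:
        self.s_q = np.atleast_2d(np.asarray(self.s_q, dtype=float))
        self.s_r = np.atleast_2d(np.asarray(self.s_r, dtype=float))


def _spread_points(state: SqrtFilterState, rule: CubatureRule) -> np.ndarray:
    """Cubature points X_i = S xi_i + x_hat, as columns of an (n, 2n) array."""
    return state.x_hat[:, None] + state.s @ rule.points.T


def predict(
    state: SqrtFilterState,
    u: np.ndarray | None,
    f_d: Callable[[np.ndarray, np.ndarray | None], np.ndarray],
    s_q: np.ndarray,
    rule: CubatureRule | None = None,
    constrain: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[SqrtFilterState, np.ndarray]:
    """Time update: propagate cubature points through f_d.

    Returns the predicted state and the centred, weighted point deviations
    (needed again by the measurement update).  ``constrain`` is applied to
    each cubature point before propagation (state-constraint clamping).
    """
    n = state.x_hat.size
    rule = rule or cubature_points(n)
    X = _spread_points(state, rule)
    Xp = np.empty_like(X)
    for i in range(X.shape[1]):
        xi = X[:, i] if constrain is None else constrain(X[:, i])
        try:
            Xp[:, i] = f_d(xi, u)
        except Exception as exc:
            raise RuntimeError(
                f"state transition failed on cubature point {i}: {exc}"
            ) from exc
    x_pred = Xp.mean(axis=1)
    Xc = (Xp - x_pred[:, None]) / np.sqrt(2 * n)
    s_pred = triangularise(np.hstack([Xc, np.atleast_2d(s_q)]))
    return SqrtFilterState(x_pred, s_pred), Xc


def update(
    state: SqrtFilterState,
    y: np.ndarray,
    h_d: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    s_r: np.ndarray,
    rule: CubatureRule | None = None,
) -> tuple[SqrtFilterState, np.ndarray]:
    """Measurement update; returns the posterior state and the innovation.

    The gain solves K S_yy S_yy^T = P_xy by two triangular solves.
    """
    n = state.x_hat.size
    rule = rule or cubature_points(n)
    X = _spread_points(state, rule)
    if callable(h_d):
        Y = np.column_stack([h_d(X[:, i]) for i in range(X.shape[1])])
    else:
        Y = np.asarray(h_d) @ X
    y_pred = Y.mean(axis=1)
    sqrt2n = np.sqrt(2 * n)
    Yc = (Y - y_pred[:, None]) / sqrt2n
    Xc = (X - state.x_hat[:, None]) / sqrt2n
    s_r = np.atleast_2d(s_r)
    s_yy = triangularise(np.hstack([Yc, s_r]))
    if np.min(np.abs(np.diag(s_yy))) < 1e-13 * max(1.0, np.abs(s_yy).max()):
        raise SingularInnovationError("innovation covariance is singular")
    p_xy = Xc @ Yc.T
    # K = (P_xy / S_yy^T) / S_yy
    z = solve_triangular(s_yy, p_xy.T, lower=True)
    k_gain = solve_triangular(s_yy, z, lower=True, trans="T").T
    innovation = np.asarray(y, dtype=float) - y_pred
    x_post = state.x_hat + k_gain @ innovation
    s_post = triangularise(np.hstack([Xc - k_gain @ Yc, k_gain @ s_r]))
    return SqrtFilterState(x_post, s_post), innovation


class SquareRootCKF:
    """Stateful SCKF wrapper around :func:`predict` and :func:`update`.

    Parameters
    ----------
    f_d : discrete state transition f_d(x, u).
    h_d : measurement map; either a callable or a constant matrix C.
    noise : square-root factors of Q and R.
    x0, s0 : initial mean and covariance square root.
    constrain : optional per-cubature-point state constraint (e.g. clamping
        muscle activations to [0, 1]); applications are counted in
        ``constraint_events``.
    """

    def __init__(
        self,
        f_d: Callable[[np.ndarray, np.ndarray | None], np.ndarray],
        h_d: Callable[[np.ndarray], np.ndarray] | np.ndarray,
        noise: NoiseFactors,
        x0: np.ndarray,
        s0: np.ndarray,
        constrain: Callable[[np.ndarray], np.ndarray] | None = None,
    ) -> None:
        self.f_d = f_d
        self.h_d = h_d
        self.noise = noise
        self.state = SqrtFilterState(np.asarray(x0, dtype=float), s0)
        self.rule = cubature_points(self.state.x_hat.size)
        self.constrain = constrain
        self.constraint_events = 0
        self.innovations: list[np.ndarray] = []

    def _counted_constrain(self, x: np.ndarray) -> np.ndarray:
        xc = self.constrain(x)
        if not np.array_equal(xc, x):
            self.constraint_events += 1
        return xc

    def step(self, y: np.ndarray, u: np.ndarray | None = None) -> SqrtFilterState:
        """One predict/update cycle: propagate with input u (held over the
        step leading to this sample) and correct with measurement y."""
        constrain = self._counted_constrain if self.constrain else None
        self.state, _ = predict(
            self.state, u, self.f_d, self.noise.s_q, self.rule, constrain
        )
        return self.correct(y)

    def correct(self, y: np.ndarray) -> SqrtFilterState:
        """Measurement update only (used for the initial sample)."""
        self.state, innov = update(
            self.state, y, self.h_d, self.noise.s_r, self.rule
        )
        self.innovations.append(innov)
        return self.state
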