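"""Independent reference implementations used as test oracles.

These deliberately avoid the package's square-root code paths: the Kalman
filter is the textbook covariance form, and the cubature filter below tracks
the full covariance matrix directly.
"""

from __future__ import annotations

import numpy as np


class TextbookKalmanFilter:
    """Standard linear Kalman filter on full covariance matrices."""

    def __init__(self, F, H, Q, R, x0, P0):
        self.F, self.H, self.Q, self.R = F, H, Q, R
        self.x = np.asarray(x0, dtype=float).copy()
        self.P = np.asarray(P0, dtype=float).copy()

    def step(self, y, u_term=None):
        x_pred = self.F @ self.x
        if u_term is not None:
            x_pred = x_pred + u_term
        P_pred = self.F @ self.P @ self.F.T + self.Q
        S = self.H @ P_pred @ self.H.T + self.R
        K = P_pred @ self.H.T @ np.linalg.inv(S)
        self.x = x_pred + K @ (y - self.H @ x_pred)
        self.P = (np.eye(self.x.size) - K @ self.H) @ P_pred
        return self.x, self.P


class PlainCKF:
    """Non-square-root cubature Kalman filter (full covariance)."""

    def __init__(self, f_d, h_d, Q, R, x0, P0):
        self.f_d, self.h_d, self.Q, self.R = f_d, h_d, Q, R
        self.x = np.asarray(x0, dtype=float).copy()
        self.P = np.asarray(P0, dtype=float).copy()

    def _points(self, x, P):
        n = x.size
        L = np.linalg.cholesky(P)
        xi = np.sqrt(n) * np.hstack([np.eye(n), -np.eye(n)])
        return x[:, None] + L @ xi

    def step(self, y, u=None):
        n = self.x.size
        X = self._points(self.x, self.P)
        Xp = np.column_stack([self.f_d(X[:, i], u) for i in range(2 * n)])
        x_pred = Xp.mean(axis=1)
        dX = Xp - x_pred[:, None]
        P_pred = dX @ dX.T / (2 * n) + self.Q
        X2 = self._points(x_pred, P_pred)
        Y = np.column_stack([self.h_d(X2[:, i]) for i in range(2 * n)])
        y_pred = Y.mean(axis=1)
        dY = Y - y_pred[:, None]
        dX2 = X2 - x_pred[:, None]
        Pyy = dY @ dY.T / (2 * n) + self.R
        Pxy = dX2 @ dY.T / (2 * n)
        K = Pxy @ np.linalg.inv(Pyy)
        self.x = x_pred + K @ (np.asarray(y) - y_pred)
        self.P = P_pred - K @ Pyy @ K.T
        return self.x, self.P


def random_stable_linear_system(n, p, rng):
    """Random discrete-time stable (F, H) pair with SPD noise covariances."""
    F = rng.standard_normal((n, n))
    F *= 0.9 / max(np.abs(np.linalg.eigvals(F)))
    H = rng.standard_normal((p, n))
    q = rng.standard_normal((n, n)) * 0.1
    Q = q @ q.T + 0.01 * np.eye(n)
    r = rng.standard_normal((p, p)) * 0.1
    R = r @ r.T + 0.01 * np.eye(p)
    return F, H, Q, R


def point_line_distance(p, a, b):
    """Generic computational-geometry point-to-line distance (projection)."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    d = b - a
    t = np.dot(p - a, d) / np.dot(d, d)
    return float(np.linalg.norm(p - (a + t * d)))
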