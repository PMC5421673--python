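import math

import numpy as np
import pytest
import sympy
from scipy.optimize import minimize

from emgstiff import dynamics as dyn
from emgstiff import kinematics as kin

SEGS = dyn.SegmentParams()


def random_configs(rng, n=10):
    qs = np.column_stack(
        [
            rng.uniform(math.radians(-20), math.radians(150), n),
            rng.uniform(0.0, math.radians(100), n),
            rng.uniform(math.radians(-60), math.radians(20), n),
        ]
    )
    return qs


class TestInertiaMatrix:
    def test_symmetry(self, rng):
        for q in random_configs(rng):
            M = dyn.inertia_matrix(q, SEGS)
            assert np.allclose(M, M.T, atol=1e-14)

    def test_positive_definite_on_grid(self, rng):
        for q in random_configs(rng, 50):
            assert np.linalg.eigvalsh(dyn.inertia_matrix(q, SEGS)).min() > 0

    def test_reduces_to_thigh_pendulum_without_distal_masses(self):
        light = dyn.SegmentParams(
            thigh=SEGS.thigh,
            shank=dyn.Segment(1e-12, SEGS.shank.com, 1e-12, SEGS.shank.length),
            foot=dyn.Segment(1e-12, SEGS.foot.com, 1e-12, SEGS.foot.length),
        )
        M = dyn.inertia_matrix(np.array([0.3, 0.4, -0.1]), light)
        expected = SEGS.thigh.mass * 0.18**2 + SEGS.thigh.inertia
        assert M[0, 0] == pytest.approx(expected, rel=1e-9)
        assert abs(M[1, 1]) < 1e-9 and abs(M[2, 2]) < 1e-9


class TestCoriolisMatrix:
    def test_zero_rates_give_zero_matrix(self, rng):
        q = random_configs(rng, 1)[0]
        assert np.allclose(dyn.coriolis_matrix(q, np.zeros(3), SEGS), 0.0)

    def test_linear_homogeneity_in_rates(self, rng):
        q = random_configs(rng, 1)[0]
        qd = rng.standard_normal(3)
        D1 = dyn.coriolis_matrix(q, qd, SEGS)
        D3 = dyn.coriolis_matrix(q, 3.0 * qd, SEGS)
        assert np.allclose(D3, 3.0 * D1, atol=1e-12)

    def test_mdot_minus_2d_skew_symmetric_along_trajectories(self, rng):
        for q in random_configs(rng, 5):
            qd = rng.standard_normal(3)
            D = dyn.coriolis_matrix(q, qd, SEGS)
            h = 1e-6
            Md = (
                dyn.inertia_matrix(q + h * qd, SEGS)
                - dyn.inertia_matrix(q - h * qd, SEGS)
            ) / (2 * h)
            S = Md - 2 * D
            assert np.abs(S + S.T).max() < 1e-6

    def test_analytic_partials_agree_with_finite_differences(self, rng):
        q = random_configs(rng, 1)[0]
        qd = rng.standard_normal(3)
        D_analytic = dyn.coriolis_matrix(q, qd, SEGS)
        D_fd = dyn.coriolis_matrix(q, qd, SEGS, fd_step=1e-6)
        assert np.allclose(D_analytic, D_fd, atol=1e-8)


class TestGravityVector:
    def test_zero_gravity_gives_zero_vector(self, rng):
        q = random_configs(rng, 1)[0]
        assert np.allclose(dyn.gravity_vector(q, SEGS, gravity=0.0), 0.0)

    def test_matches_numerical_gradient_of_potential(self, rng):
        for q in random_configs(rng, 5):
            k = dyn.gravity_vector(q, SEGS)
            h = 1e-6
            fd = np.array(
                [
                    (
                        dyn.potential_energy(q + h * e, SEGS)
                        - dyn.potential_energy(q - h * e, SEGS)
                    )
                    / (2 * h)
                    for e in np.eye(3)
                ]
            )
            assert np.allclose(k, fd, rtol=1e-6, atol=1e-8)

    def test_vanishes_at_hanging_equilibrium(self):
        """k = dP/dq must be zero at the numerically located minimum of P."""
        res = minimize(
            lambda q: dyn.potential_energy(q, SEGS),
            x0=np.array([0.0, 0.1, -0.3]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert np.allclose(dyn.gravity_vector(res.x, SEGS), 0.0, atol=1e-4)


class TestJointTorques:
    def test_viscous_zero_at_rest(self):
        assert dyn.viscous_torque(0.0, 1.5, 1.2) == 0.0

    def test_viscous_odd_symmetry(self):
        assert dyn.viscous_torque(-0.8, 1.5, 1.3) == pytest.approx(
            -dyn.viscous_torque(0.8, 1.5, 1.3)
        )

    def test_viscous_direct_substitution(self):
        assert dyn.viscous_torque(2.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_viscous_element_dissipates_in_assembly(self, model):
        """The power q̇ tau_V injected by the assembled viscous torque must be
        negative whatever the sign of the rate."""
        x = np.zeros(16)
        u = np.zeros(15)
        for rate in (0.7, -0.7):
            x[3] = rate
            base = model.state_derivative(x, u, clamp=True)
            p = model.passive
            tau_v = -dyn.viscous_torque(rate, p.k_v_ankle, p.n_v_ankle)
            assert rate * tau_v < 0

    def test_knee_elastic_degenerate_parameters(self):
        p = dyn.PassiveTorqueParams(
            a1k=-1e3, a2k=-1e3, fk=-1e3, ek=5.0
        )
        assert dyn.elastic_torque_knee(0.3, 0.5, -0.2, p) == pytest.approx(5.0)

    def test_knee_elastic_matches_symbolic_evaluation(self, rng):
        """Random parameter draws against a sympy evaluation of the
        double-exponential expression."""
        q1s, q2s, q3s = sympy.symbols("q1 q2 q3")
        names = ["a1k", "b1k", "c1k", "d1k", "a2k", "b2k", "c2k", "d2k",
                 "ek", "fk", "gk"]
        for _ in range(5):
            vals = {n: float(rng.uniform(-2, 1)) for n in names}
            p = dyn.PassiveTorqueParams(**vals)
            expr = (
                sympy.exp(vals["a1k"] + vals["b1k"] * q1s + vals["c1k"] * q2s
                          + vals["d1k"] * q3s)
                - sympy.exp(vals["a2k"] + vals["b2k"] * q1s + vals["c2k"] * q2s
                            + vals["d2k"] * q3s)
                + vals["ek"]
                - sympy.exp(vals["fk"] + vals["gk"] * q2s)
            )
            q = rng.uniform(-0.5, 0.5, 3)
            expected = float(expr.subs({q1s: q[0], q2s: q[1], q3s: q[2]}))
            assert dyn.elastic_torque_knee(*q, p) == pytest.approx(expected, rel=1e-12)

    def test_knee_elastic_biarticular_coupling(self):
        p = dyn.PassiveTorqueParams()
        t0 = dyn.elastic_torque_knee(0.0, 0.3, 0.0, p)
        t1 = dyn.elastic_torque_knee(0.5, 0.3, 0.0, p)
        assert t0 != pytest.approx(t1)

    def test_ankle_elastic_degenerate_parameters(self):
        p = dyn.PassiveTorqueParams(a1a=-1e3, a2a=-1e3, da=-1.0)
        assert dyn.elastic_torque_ankle(0.2, -0.1, p) == pytest.approx(-1.0)

    def test_ankle_elastic_slope_matches_finite_difference(self):
        p = dyn.PassiveTorqueParams()
        q2, q3 = 0.4, -0.25
        h = 1e-7
        fd = (
            dyn.elastic_torque_ankle(q2, q3 + h, p)
            - dyn.elastic_torque_ankle(q2, q3 - h, p)
        ) / (2 * h)
        assert dyn.delastic_torque_ankle_dq3(q2, q3, p) == pytest.approx(fd, rel=1e-6)

    def test_ankle_elastic_depends_on_knee_angle(self):
        p = dyn.PassiveTorqueParams()
        assert dyn.elastic_torque_ankle(0.0, 0.25, p) != pytest.approx(
            dyn.elastic_torque_ankle(0.8, 0.25, p)
        )

    def test_elastic_overflow_guarded(self):
        p = dyn.PassiveTorqueParams()
        with pytest.raises(OverflowError):
            dyn.elastic_torque_knee(0.0, -10.0, 0.0, p)

    def test_active_torque_trivials(self):
        assert dyn.active_torque([0.05, 0.04], [1, -1], [0.0, 0.0]) == 0.0
        assert dyn.active_torque([0.05], [1], [100.0]) == pytest.approx(5.0)
        assert dyn.active_torque([0.05, 0.05], [1, -1], [80.0, 80.0]) == (
            pytest.approx(0.0)
        )
        with pytest.raises(ValueError):
            dyn.active_torque([0.05], [1, -1], [1.0, 2.0])

    def test_grf_torque_trivials(self):
        grf0 = dyn.GroundReaction([0.1, 0.0, 0.0], [0.0, 0.0, 0.0])
        axis = np.array([0.0, 0.0, 1.0])
        assert dyn.grf_torque(np.zeros(3), axis, grf0) == 0.0
        through = dyn.GroundReaction([0.0, -0.5, 0.0], [0.0, 100.0, 0.0])
        assert dyn.grf_torque(np.zeros(3), axis, through) == pytest.approx(0.0)
        lever = dyn.GroundReaction([1.0, 0.0, 0.0], [0.0, 10.0, 0.0])
        assert dyn.grf_torque(np.zeros(3), axis, lever) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            dyn.grf_torque(np.zeros(3), np.array([0.0, 0.0, 2.0]), lever)

    def test_grf_requires_finite_components(self):
        with pytest.raises(ValueError):
            dyn.GroundReaction([np.nan, 0, 0], [0, 0, 0])


class TestReducedDynamics:
    def test_coupling_vanishes_without_hip_motion(self, rng):
        """With q̈1 = q̇1 = 0 the reduced torque is just (tau2, tau3):
        the accelerations solve the plain 2x2 system."""
        q_hat = np.array([0.4, -0.2])
        qd_hat = np.array([0.3, -0.1])
        tau2, tau3 = 1.5, -0.7
        got = dyn.reduced_dynamics(q_hat, qd_hat, (0.2, 0.0, 0.0), tau2, tau3, SEGS)
        q = np.array([0.2, *q_hat])
        qd = np.array([0.0, *qd_hat])
        M = dyn.inertia_matrix(q, SEGS)
        D = dyn.coriolis_matrix(q, qd, SEGS)
        k = dyn.gravity_vector(q, SEGS)
        rhs = np.array([tau2, tau3]) - k[1:] - D[1:, 1:] @ qd_hat
        assert np.allclose(got, np.linalg.solve(M[1:, 1:], rhs))

    def test_matches_rows_of_full_euler_lagrange_system(self, rng):
        """Full-system oracle: substituting the reduced accelerations back
        into rows 2-3 of M q̈ + D q̇ + k = tau must balance exactly."""
        for _ in range(5):
            q = random_configs(rng, 1)[0]
            qd = rng.standard_normal(3) * 0.5
            q1dd = float(rng.standard_normal())
            tau2, tau3 = rng.standard_normal(2)
            qdd_hat = dyn.reduced_dynamics(
                q[1:], qd[1:], (q[0], qd[0], q1dd), tau2, tau3, SEGS
            )
            qdd = np.array([q1dd, *qdd_hat])
            M = dyn.inertia_matrix(q, SEGS)
            D = dyn.coriolis_matrix(q, qd, SEGS)
            k = dyn.gravity_vector(q, SEGS)
            residual = (M @ qdd + D @ qd + k)[1:] - np.array([tau2, tau3])
            assert np.allclose(residual, 0.0, atol=1e-9)

    def test_static_equilibrium_gives_zero_acceleration(self):
        q_hat = np.array([0.3, -0.2])
        q = np.array([0.1, *q_hat])
        k = dyn.gravity_vector(q, SEGS)
        got = dyn.reduced_dynamics(
            q_hat, np.zeros(2), (0.1, 0.0, 0.0), k[1], k[2], SEGS
        )
        assert np.allclose(got, 0.0, atol=1e-12)


class TestStateDerivative:
    def test_kinematic_rows_are_structural(self, model, rng):
        x = np.zeros(16)
        x[0], x[1] = 0.3, -0.2
        x[2], x[3] = rng.standard_normal(2)
        xd = model.state_derivative(x, np.zeros(15), clamp=True)
        assert xd[0] == x[2] and xd[1] == x[3]

    def test_passive_equilibrium_is_stationary(self, model):
        """All-zero EMG at the numerically located passive equilibrium gives
        a (near) zero state derivative."""
        from scipy.optimize import root

        def residual(q_hat):
            x = np.zeros(16)
            x[0], x[1] = q_hat
            return model.state_derivative(x, np.zeros(15), clamp=True)[2:4]

        sol = root(residual, x0=np.array([0.1, -0.4]), tol=1e-12)
        assert sol.success
        x = np.zeros(16)
        x[0], x[1] = sol.x
        xd = model.state_derivative(x, np.zeros(15), clamp=True)
        assert np.allclose(xd, 0.0, atol=1e-8)

    def test_removing_grf_equals_zero_external_torque(self, model):
        x = np.zeros(16)
        x[0], x[1] = 0.3, -0.2
        u = np.zeros(15)
        xd_no = model.state_derivative(x, u, clamp=True)
        u_grf = u.copy()
        u_grf[9:12] = [0.1, -0.8, 0.0]
        u_grf[12:15] = [5.0, 40.0, 0.0]
        xd_grf = model.state_derivative(x, u_grf, clamp=True)
        assert not np.allclose(xd_no[2:4], xd_grf[2:4])
        u_zero_force = u_grf.copy()
        u_zero_force[12:15] = 0.0
        assert np.allclose(
            model.state_derivative(x, u_zero_force, clamp=True), xd_no
        )

    def test_bad_dimensions_rejected(self, model):
        with pytest.raises(ValueError):
            model.state_derivative(np.zeros(15), np.zeros(15))


class TestDiscretisation:
    def test_zero_field_is_identity(self):
        x = np.array([1.0, -2.0])
        assert np.allclose(dyn.discretise_step(x, np.zeros(2), 0.01), x)

    def test_linear_decay_direct_substitution(self):
        assert dyn.discretise_step(np.array([1.0]), np.array([-1.0]), 0.01)[
            0
        ] == pytest.approx(0.99)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            dyn.discretise_step(np.zeros(2), np.zeros(2), 0.0)

    def test_first_order_convergence_to_reference_solution(self):
        """Halving the Euler step roughly halves the error against a
        high-accuracy reference for a smooth nonlinear field."""
        f = lambda x: np.array([-x[0] + 0.3 * math.sin(x[1]), -0.5 * x[1]])
        from scipy.integrate import solve_ivp

        ref = solve_ivp(
            lambda t, x: f(x), (0, 1.0), [1.0, 0.8], rtol=1e-12, atol=1e-12
        ).y[:, -1]

        def euler(ts):
            x = np.array([1.0, 0.8])
            for _ in range(int(round(1.0 / ts))):
                x = dyn.discretise_step(x, f(x), ts)
            return x

        err1 = np.linalg.norm(euler(0.01) - ref)
        err2 = np.linalg.norm(euler(0.005) - ref)
        assert 0.4 < err2 / err1 < 0.6


class TestEnergyConservation:
    @staticmethod
    def _drift(ts: float) -> float:
        """Energy drift of the torque-free (gravity only) chain under
        explicit Euler over one second."""
        q = np.array([0.2, 0.4, -0.3])
        qd = np.zeros(3)
        e0 = dyn.total_energy(q, qd, SEGS)
        n = int(round(1.0 / ts))
        drift = 0.0
        for _ in range(n):
            M = dyn.inertia_matrix(q, SEGS)
            D = dyn.coriolis_matrix(q, qd, SEGS)
            k = dyn.gravity_vector(q, SEGS)
            qdd = np.linalg.solve(M, -D @ qd - k)
            q = q + ts * qd
            qd = qd + ts * qdd
            drift = max(drift, abs(dyn.total_energy(q, qd, SEGS) - e0))
        return drift

    def test_drift_halves_with_euler_step(self):
        d1 = self._drift(1e-3)
        d2 = self._drift(5e-4)
        assert 0.3 < d2 / d1 < 0.7
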