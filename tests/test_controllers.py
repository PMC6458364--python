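"""Balance controllers, Poincare map machinery, and the discrete LQR."""

import math

import numpy as np
import pytest
from scipy.linalg import solve_discrete_are

from btslip.controllers import (ControlGains, FallError, PreflexLibrary,
                                StepToStepMap, adapt_gains, fmch_torque,
                                linearize, nmf_torque, poincare_map,
                                solve_dlqr, vbla_direction,
                                NMF_GAINS_CALIBRATED)
from btslip.params import (FMCHParams, MuscleParams, WalkerParams,
                           default_ham, default_rf)

from conftest import walker_state


class TestVBLA:
    def test_mu_one_points_straight_down(self):
        o = vbla_direction((3.0, 1.0), 1.0)
        np.testing.assert_allclose(o, [0.0, -1.0], atol=1e-12)

    def test_mu_zero_parallel_to_velocity(self):
        o = vbla_direction((1.0, 0.0), 0.0)
        np.testing.assert_allclose(o, [1.0, 0.0], atol=1e-12)

    def test_published_weighting_angle(self):
        # mu = 0.34, V = (1, 0): leg ~11.2 deg in front of vertical
        o = vbla_direction((1.0, 0.0), 0.34, g=9.81)
        ang = math.degrees(math.atan2(o[0], -o[1]))
        assert ang == pytest.approx(math.degrees(math.atan(0.66 / 3.3354)),
                                    abs=0.05)
        assert ang == pytest.approx(11.2, abs=0.1)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            vbla_direction((0.0, 0.0), 0.0)
        with pytest.raises(ValueError):
            vbla_direction((1.0, 0.0), 1.5)


class TestFMCHTorque:
    def test_swing_leg_exerts_nothing(self):
        assert fmch_torque(0.0, 3.0, FMCHParams(G=0.5, phi_h0=3.1)) == 0.0

    def test_rest_angle(self):
        assert fmch_torque(700.0, 3.1, FMCHParams(G=0.5, phi_h0=3.1)) == 0.0

    def test_bilinear_scaling(self):
        p = FMCHParams(G=0.001, phi_h0=3.2)
        base = fmch_torque(800.0, 3.1, p)
        assert base == pytest.approx(0.001 * 800.0 * 0.1)
        assert fmch_torque(1600.0, 3.1, p) == pytest.approx(2 * base)
        assert fmch_torque(800.0, 3.0, p) == pytest.approx(2 * base)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            fmch_torque(-1.0, 3.0, FMCHParams())


class TestNMFTorque:
    def test_symmetric_antagonists_cancel(self):
        """Equal gains and identical muscle geometry give zero torque."""
        rf = default_rf()
        ham = MuscleParams(name="HAM", phi_ref=rf.phi_ref)
        # HAM length law mirrors RF's; with equal phi_ref and equal
        # activations the isometric forces match at phi_h = phi_ref
        p = WalkerParams(rf=rf, ham=ham)
        phi = rf.phi_ref - math.pi / 2
        hip_x = -p.model.r_h * math.cos(phi)
        st = walker_state(y=1.08, vx=0.0, phi=phi,
                          activations=[0.3, 0.3, 0.0, 0.0],
                          foot_x=(hip_x, 0.0))
        # leg vertical under the hip -> phi_h = phi + pi/2 = phi_ref,
        # and a stationary hip keeps phidot_h = 0
        assert nmf_torque(st, 0, p) == pytest.approx(0.0, abs=1e-9)

    def test_baseline_activation_torque_value(self):
        """At baseline activation the torque equals the analytic
        composition r0 (A_ham Fmax fl_ham - A_rf Fmax fl_rf) at the
        stated geometry (phidot_h = 0)."""
        from btslip.muscle import force_length, muscle_lengths
        p = WalkerParams()
        a0 = 0.01
        st = walker_state(y=1.08, vx=0.0, phi=math.pi / 2,
                          activations=[a0, a0, 0.0, 0.0])
        phi_h = math.pi  # vertical leg below upright trunk
        L_rf, L_ham = muscle_lengths(phi_h, p.rf, p.ham)
        expected = p.rf.r0 * p.rf.F_max * a0 * (
            force_length(L_ham, p.ham) - force_length(L_rf, p.rf))
        assert nmf_torque(st, 0, p) == pytest.approx(expected, rel=1e-9)

    def test_matches_engine_recording(self, nmf_cycle, nmf_results):
        """The public torque composition reproduces the kernel's recorded
        stance torques along the simulated cycle."""
        from btslip.engine import WalkerState
        p = nmf_results.model.params
        rows = nmf_cycle.iloc[::40]
        checked = 0
        for _, r in rows.iterrows():
            for leg in (0, 1):
                if r[f"contact_{leg}"] < 1 or not np.isfinite(r[f"tau_{leg}"]):
                    continue
                acts = np.zeros(4)
                acts[2 * leg] = r[f"A_rf_{leg}"]
                acts[2 * leg + 1] = r[f"A_ham_{leg}"]
                foot = np.zeros(2)
                foot[leg] = r[f"foot_x_{leg}"]
                st = WalkerState(x=r["x"], y=r["y"], vx=r["vx"], vy=r["vy"],
                                 phi=r["phi"], phidot=r["phidot"],
                                 activations=acts, foot_x=foot,
                                 contact=np.array([1, 1]))
                assert nmf_torque(st, leg, p) == pytest.approx(
                    r[f"tau_{leg}"], rel=1e-9, abs=1e-9)
                checked += 1
        assert checked > 10


class TestStepMap:
    def test_fixed_point_property(self, nmf_results):
        ctx = StepToStepMap(nmf_results.model.params, kind="nmf")
        S = nmf_results.S_star
        out = poincare_map(S, nmf_results.U_star, ctx)
        assert np.linalg.norm(out - S) < 1e-7

    def test_semigroup_two_applications(self, nmf_results):
        ctx = StepToStepMap(nmf_results.model.params, kind="nmf")
        S = nmf_results.S_star + np.array([1e-3, 0, 0, 0, 0])
        once = ctx(ctx(S))
        # the same perturbed state advanced twice equals the 2-step map
        again = ctx(ctx(S.copy()))
        np.testing.assert_allclose(once, again, rtol=0, atol=1e-12)

    def test_fall_raises_fall_error(self):
        ctx = StepToStepMap(WalkerParams(), kind="nmf")
        with pytest.raises(FallError):
            ctx(np.array([1.0, 1.09, 0.0, 0.9, -2.0]))

    def test_damped_directions_contract(self, fmch_results):
        """A perturbation restricted to the contracting eigenspace shrinks
        under the map (the FMCH's speed direction is neutral, the rest are
        damped)."""
        A = fmch_results.A_s
        w, V = np.linalg.eig(A)
        i = int(np.argsort(np.abs(w))[-2])  # largest damped eigenvalue
        v = np.real(V[:, i])
        v /= np.linalg.norm(v)
        ctx = StepToStepMap(fmch_results.model.params, kind="fmch")
        S = fmch_results.S_star
        eps = 1e-4
        out = ctx(S + eps * v)
        assert np.linalg.norm(out - S) < eps


class TestLinearize:
    @staticmethod
    def _quadratic_map(S, U=None):
        A = np.array([[0.9, 0.1, 0.0, 0.0, 0.0],
                      [0.0, 0.8, 0.2, 0.0, 0.0],
                      [0.0, 0.0, 0.7, 0.1, 0.0],
                      [0.1, 0.0, 0.0, 0.6, 0.1],
                      [0.0, 0.1, 0.0, 0.0, 0.5]])
        B = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.2],
                      [0.0, 0.3], [0.2, 0.0]])
        S = np.asarray(S, float)
        U = np.zeros(2) if U is None else np.asarray(U, float)
        return A @ S + B @ U + 0.3 * S * S

    def test_recovers_analytic_jacobian(self):
        S0 = np.full(5, 0.1)
        U0 = np.array([0.2, 0.1])
        A_num, B_num = linearize(self._quadratic_map, S0, U0, h_rel=1e-5)
        A_exact = np.array([[0.9, 0.1, 0.0, 0.0, 0.0],
                            [0.0, 0.8, 0.2, 0.0, 0.0],
                            [0.0, 0.0, 0.7, 0.1, 0.0],
                            [0.1, 0.0, 0.0, 0.6, 0.1],
                            [0.0, 0.1, 0.0, 0.0, 0.5]]) \
            + np.diag(0.6 * S0)
        B_exact = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.2],
                            [0.0, 0.3], [0.2, 0.0]])
        np.testing.assert_allclose(A_num, A_exact, atol=1e-9)
        np.testing.assert_allclose(B_num, B_exact, atol=1e-7)

    def test_central_difference_order(self):
        """Doubling h changes the Jacobian entries by O(h^2) on a cubic."""
        fun = lambda S, U=None: np.asarray(S) ** 3 + np.asarray(S)
        S0 = np.full(5, 0.5)
        errs = []
        for h in (1e-3, 2e-3):
            A, _ = linearize(fun, S0, np.array([1.0, 1.0]), h_rel=h)
            exact = np.diag(3 * S0 ** 2 + 1.0)
            errs.append(np.max(np.abs(A - exact)))
        assert errs[1] / errs[0] == pytest.approx(4.0, rel=0.05)

    def test_stable_gait_spectral_radius_below_one_off_neutral(self, fmch_results):
        lams = np.sort(np.abs(fmch_results.eigenvalues))[::-1]
        assert lams[0] == pytest.approx(1.0, abs=1e-3)  # neutral speed mode
        assert np.all(lams[1:] < 1.0)


class TestDLQR:
    def test_scalar_golden_ratio(self):
        A = np.array([[1.0]])
        B = np.array([[1.0]])
        Q = R = np.array([[1.0]])
        K, P = solve_dlqr(A, B, Q, R)
        assert P[0, 0] == pytest.approx((1 + math.sqrt(5)) / 2, abs=1e-10)
        assert K[0, 0] == pytest.approx(P[0, 0] / (P[0, 0] + 1), abs=1e-10)

    def test_no_actuation_reduces_to_lyapunov(self):
        A = np.diag([0.5, -0.3])
        B = np.zeros((2, 1))
        Q = np.eye(2)
        R = np.eye(1)
        K, P = solve_dlqr(A, B, Q, R)
        np.testing.assert_allclose(K, 0.0, atol=1e-12)
        np.testing.assert_allclose(P, Q + A.T @ P @ A, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_riccati_solver(self, seed):
        """Fixed-point iteration agrees with scipy's DARE to 1e-8 on random
        stabilizable systems up to 5x2."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6), rng.integers(1, 3)
        A = rng.normal(0, 0.6, (n, n))
        B = rng.normal(0, 1.0, (n, m))
        Q = np.eye(n)
        R = np.eye(m)
        K, P = solve_dlqr(A, B, Q, R, tol=1e-14)
        P_ref = solve_discrete_are(A, B, Q, R)
        assert np.max(np.abs(P - P_ref)) < 1e-8
        rho = np.max(np.abs(np.linalg.eigvals(A - B @ K)))
        assert rho < 1.0

    def test_closed_loop_stabilizes_walker_map(self, adaptive_results):
        A, B, K = adaptive_results.A_s, adaptive_results.B_s, adaptive_results.K
        assert np.max(np.abs(np.linalg.eigvals(A))) > 1.0  # open loop drifts
        assert np.max(np.abs(np.linalg.eigvals(A - B @ K))) < 1.0

    def test_nonconvergence_reports_spectral_radius(self):
        A = np.array([[2.0]])
        B = np.array([[0.0]])  # unstabilizable
        with pytest.raises(RuntimeError, match="spectral radius"):
            solve_dlqr(A, B, np.eye(1), np.eye(1), max_iter=200)

    def test_rejects_semidefinite_R(self):
        with pytest.raises(ValueError):
            solve_dlqr(np.eye(2), np.ones((2, 1)), np.eye(2),
                       np.zeros((1, 1)))


class TestAdaptGains:
    def test_no_adaptation_on_the_cycle(self):
        U = np.array([2e-3, 1e-3])
        K = np.ones((2, 5))
        out = adapt_gains(np.zeros(5), np.zeros(5), U, K)
        np.testing.assert_allclose(out, U)

    def test_zero_K_reduces_to_plain_nmf(self):
        U = np.array([2e-3, 1e-3])
        out = adapt_gains(np.ones(5), np.zeros(5), U, np.zeros((2, 5)))
        np.testing.assert_allclose(out, U)

    def test_gain_floor_clamps(self):
        U = np.array([1e-3, 1e-3])
        K = np.full((2, 5), 1.0)
        out = adapt_gains(np.full(5, 1.0), np.zeros(5), U, K, gain_floor=0.0)
        np.testing.assert_allclose(out, 0.0)

    def test_control_gains_container(self):
        g = ControlGains(G_HAM=2e-3, G_RF=1e-3)
        np.testing.assert_allclose(g.as_array(), [2e-3, 1e-3])
        assert ControlGains.from_array([1e-3, 5e-4]).G_RF == 5e-4
        with pytest.raises(ValueError):
            ControlGains(G_HAM=-1.0, G_RF=0.0)


class TestPreflex:
    def test_missing_library_rejected(self):
        from btslip.controllers import PreflexController
        with pytest.raises(ValueError):
            PreflexController(None)

    def test_csv_roundtrip(self, preflex_results, tmp_path):
        lib = preflex_results.library
        lib.to_csv(tmp_path / "lib.csv")
        back = PreflexLibrary.from_csv(tmp_path / "lib.csv")
        np.testing.assert_allclose(back.t, lib.t)
        np.testing.assert_allclose(back.a_ham, lib.a_ham)
        assert back.stride_duration == pytest.approx(lib.stride_duration)

    def test_replay_holds_last_value_beyond_record(self, preflex_results):
        lib = preflex_results.library
        end = lib.activations_at(lib.t[-1] + 10.0)
        assert end == pytest.approx((lib.a_rf[-1], lib.a_ham[-1]))

    def test_replay_reproduces_nmf_cycle(self, preflex_results, nmf_results):
        """Replaying the recorded activations on the unperturbed gait
        reproduces the closed-loop cycle to interpolation error."""
        run = preflex_results.simulate(n_steps=16)
        assert run.n_steps_completed == 16
        assert run.mean_speed == pytest.approx(nmf_results.cycle.mean_speed,
                                               rel=2e-3)
        d = run.steps["duration"].iloc[2:8].mean()
        d_ref = nmf_results.cycle.steps["duration"].iloc[2:8].mean()
        assert d == pytest.approx(d_ref, rel=2e-3)
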