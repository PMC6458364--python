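"""Hill-type muscle curves, hip geometry and the reflex pathway."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from btslip.muscle import (ForceHistory, activation_derivative, ce_force,
                           delayed_leg_force, force_length, force_velocity,
                           hip_torque, muscle_lengths, muscle_velocities,
                           stimulation)
from btslip.params import MuscleParams, ReflexParams
from btslip.params import default_ham, default_rf


@pytest.fixture(scope="module")
def mp():
    return MuscleParams()


class TestForceLength:
    def test_unity_at_optimal_length(self, mp):
        assert force_length(mp.l_opt, mp) == 1.0

    @pytest.mark.parametrize("sign", [+1, -1])
    def test_bell_width_value(self, mp, sign):
        # exp(c) = 0.05 at l_opt (1 +- w)
        assert force_length(mp.l_opt * (1 + sign * mp.w), mp) == \
            pytest.approx(0.05)

    @given(st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_about_optimum(self, dz):
        mp = MuscleParams()
        lo = mp.l_opt * (1 - dz * mp.w)
        hi = mp.l_opt * (1 + dz * mp.w)
        assert force_length(lo, mp) == pytest.approx(force_length(hi, mp))

    def test_bounded_in_unit_interval(self, mp):
        for l in np.linspace(0.02, 0.3, 50):
            assert 0.0 <= force_length(l, mp) <= 1.0

    def test_rejects_nonpositive_length(self, mp):
        with pytest.raises(ValueError):
            force_length(0.0, mp)


class TestForceVelocity:
    def test_isometric_unity_from_both_branches(self, mp):
        assert force_velocity(0.0, mp) == pytest.approx(1.0)
        assert force_velocity(-1e-12, mp) == pytest.approx(1.0)
        assert force_velocity(+1e-12, mp) == pytest.approx(1.0)

    def test_zero_at_max_shortening(self, mp):
        assert force_velocity(mp.v_max, mp) == 0.0
        assert force_velocity(1.5 * mp.v_max, mp) == 0.0  # clamped

    def test_half_max_shortening_value(self, mp):
        # (1/2) / (1 + kappa/2) with kappa = 5
        assert force_velocity(mp.v_max / 2, mp) == pytest.approx(0.5 / 3.5)

    def test_concentric_monotone_decreasing_with_speed(self, mp):
        v = np.linspace(mp.v_max, 0.0, 40)
        f = [force_velocity(x, mp) for x in v]
        assert np.all(np.diff(f) > 0)  # toward v=0 force rises

    def test_eccentric_monotone_and_bounded(self, mp):
        v = np.linspace(0.0, 30.0, 80)
        f = [force_velocity(x, mp) for x in v]
        assert np.all(np.diff(f) > 0)
        plateau = mp.N_ecc + (mp.N_ecc - 1) / (7.56 * mp.kappa)
        assert f[-1] < plateau


class TestCEForce:
    def test_zero_activation_zero_force(self, mp):
        assert ce_force(0.0, 0.08, -0.5, mp) == 0.0

    def test_reference_point_gives_f_max(self, mp):
        assert ce_force(1.0, mp.l_opt, 0.0, mp) == pytest.approx(2000.0)

    def test_product_form(self, mp):
        # A = 0.5 at the bell edge, isometric: 0.5 * 2000 * 0.05
        val = ce_force(0.5, mp.l_opt * (1 + mp.w), 0.0, mp)
        assert val == pytest.approx(50.0)

    def test_rejects_activation_outside_unit_interval(self, mp):
        with pytest.raises(ValueError):
            ce_force(1.2, mp.l_opt, 0.0, mp)


class TestGeometry:
    def test_reference_angles_give_rest_lengths(self):
        rf, ham = default_rf(), default_ham()
        assert muscle_lengths(rf.phi_ref, rf, ham)[0] == pytest.approx(0.11)
        assert muscle_lengths(ham.phi_ref, rf, ham)[1] == pytest.approx(0.11)

    def test_lever_scaling(self):
        rf, ham = default_rf(), default_ham()
        # rho r0 = 0.05 m/rad
        L_rf, _ = muscle_lengths(rf.phi_ref + 0.2, rf, ham)
        assert L_rf == pytest.approx(0.12)

    def test_antagonistic_length_signs(self):
        rf, ham = default_rf(), default_ham()
        L1 = muscle_lengths(3.1, rf, ham)
        L2 = muscle_lengths(3.3, rf, ham)
        assert L2[0] > L1[0]   # RF lengthens with extension
        assert L2[1] < L1[1]   # HAM shortens

    def test_velocities_are_length_derivatives(self):
        rf, ham = default_rf(), default_ham()
        v_rf, v_ham = muscle_velocities(2.0, rf, ham)
        assert v_rf == pytest.approx(0.1 * 0.5 * 2.0)
        assert v_ham == pytest.approx(-0.1 * 0.5 * 2.0)

    def test_geometry_misconfiguration_rejected(self):
        rf, ham = default_rf(), default_ham()
        with pytest.raises(ValueError):
            muscle_lengths(rf.phi_ref - 5.0, rf, ham)


class TestHipTorque:
    def test_antagonist_balance(self):
        assert hip_torque(123.0, 123.0, 0.1) == 0.0

    def test_signs(self):
        assert hip_torque(0.0, 100.0, 0.1) == pytest.approx(+10.0)
        assert hip_torque(200.0, 0.0, 0.1) == pytest.approx(-20.0)

    def test_rejects_negative_forces(self):
        with pytest.raises(ValueError):
            hip_torque(-1.0, 0.0, 0.1)


class TestStimulation:
    def test_bias_at_zero_force(self):
        rx = ReflexParams()
        assert stimulation(0.0, rx.G_HAM, rx.STIM0) == pytest.approx(0.01)

    def test_gain_times_fmax(self):
        rx = ReflexParams()
        assert stimulation(2000.0, rx.G_HAM, rx.STIM0) == \
            pytest.approx(0.01 + 0.936)

    def test_saturation(self):
        rx = ReflexParams()
        assert stimulation(1e9, rx.G_HAM, rx.STIM0) == 1.0
        assert stimulation(0.0, 0.0, -0.5) == 0.0


class TestActivationDynamics:
    def test_fixed_point(self):
        assert activation_derivative(0.3, 0.3, 1e-3) == 0.0

    def test_first_order_step_response(self):
        # closed form A(t) = s (1 - exp(-t/T)) integrated with small steps
        T, s, dt = 1e-3, 0.7, 1e-6
        A = 0.0
        for _ in range(int(T / dt)):
            A += dt * activation_derivative(A, s, T)
        assert A == pytest.approx(s * (1 - math.exp(-1.0)), rel=1e-3)

    def test_settles_within_five_time_constants(self):
        T, s, dt = 1e-3, 0.4, 1e-6
        A = 0.0
        for _ in range(int(5 * T / dt)):
            A += dt * activation_derivative(A, s, T)
        assert abs(A - s) < 0.01 * s

    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_activation_stays_in_unit_interval(self, stims):
        """First-order lag toward values in [0,1] cannot leave [0,1]."""
        A, dt, T = 0.5, 2e-4, 1e-3
        for s in stims:
            for _ in range(20):
                A += dt * activation_derivative(A, s, T)
            assert -1e-9 <= A <= 1.0 + 1e-9

    def test_rejects_nonpositive_time_constant(self):
        with pytest.raises(ValueError):
            activation_derivative(0.1, 0.2, 0.0)


class TestDelayedForce:
    def test_zero_delay_returns_current(self):
        h = ForceHistory()
        for t, f in [(0.0, 10.0), (0.1, 20.0), (0.2, 40.0)]:
            h.append(t, f)
        assert delayed_leg_force(h, 0.2, 0.0) == 40.0

    def test_constant_record(self):
        h = ForceHistory()
        for t in np.linspace(0, 1, 11):
            h.append(t, 55.0)
        assert delayed_leg_force(h, 0.9, 0.25) == pytest.approx(55.0)

    def test_linear_ramp_exact_under_interpolation(self):
        a = 123.0
        h = ForceHistory()
        for t in np.linspace(0, 1, 7):
            h.append(t, a * t)
        for tq, dp in [(0.9, 0.3), (0.5, 0.1), (1.0, 0.77)]:
            assert delayed_leg_force(h, tq, dp) == pytest.approx(a * (tq - dp))

    def test_before_record_start_is_zero(self):
        h = ForceHistory()
        h.append(1.0, 99.0)
        assert delayed_leg_force(h, 1.0, 2.0) == 0.0
        assert delayed_leg_force(ForceHistory(), 0.0, 0.0) == 0.0

    def test_rejects_decreasing_times(self):
        h = ForceHistory()
        h.append(1.0, 1.0)
        with pytest.raises(ValueError):
            h.append(0.5, 2.0)


def test_kernel_history_matches_reference_interpolation():
    """The compiled ring-buffer lookup agrees with the pure-Python record."""
    from btslip import _core
    rng = np.random.default_rng(3)
    ts = np.sort(rng.uniform(0, 1, 40))
    fs = rng.uniform(0, 900, 40)
    hist_t = np.zeros((2, 64))
    hist_F = np.zeros((2, 64))
    hist_n = np.zeros(2, dtype=np.int64)
    ref = ForceHistory()
    for t, f in zip(ts, fs):
        _core.hist_write(hist_t, hist_F, hist_n, 0, t, f)
        ref.append(t, f)
    for tq in rng.uniform(0.05, 0.99, 25):
        assert _core.hist_lookup(hist_t, hist_F, hist_n, 0, tq) == \
            pytest.approx(ref.value_at(tq), rel=1e-12)
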