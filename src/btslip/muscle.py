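"""Hill-type contractile element, RF/HAM hip geometry, and the reflex
stimulation -> activation (excitation-contraction coupling) pathway.

The muscle-tendon unit is reduced to its contractile element (no series
elasticity), so the CE length equals the geometric muscle length given by
the hip angle and the CE velocity is its exact time derivative:
``v_RF = +rho r0 phidot_h``, ``v_HAM = -rho r0 phidot_h``.
"""

from __future__ import annotations

from bisect import bisect_right

from . import _core
from .params import MuscleParams

__all__ = [
    "force_length",
    "force_velocity",
    "ce_force",
    "muscle_lengths",
    "muscle_velocities",
    "hip_torque",
    "stimulation",
    "activation_derivative",
    "ForceHistory",
    "delayed_leg_force",
]


def force_length(l_ce: float, p: MuscleParams) -> float:
    """Bell-shaped force-length factor: 1 at ``l_opt``, ``exp(c)`` at
    ``l_opt (1 +- w)``, symmetric in the scaled offset."""
    if l_ce <= 0:
        raise ValueError("CE length must be positive")
    return _core.fl_curve(l_ce, p.l_opt, p.w, p.c)


def force_velocity(v_ce: float, p: MuscleParams) -> float:
    """Hill force-velocity factor.

    ``v_ce`` is lengthening-positive in the same units as ``p.v_max``
    (optimal lengths per second; the relation is scale-invariant so m/s
    works as long as ``v_max`` is converted consistently).  Output is
    clamped to 0 for shortening faster than ``v_max`` and approaches the
    eccentric plateau ``N + (N-1)/(7.56 kappa)`` for fast lengthening.
    """
    return _core.fv_curve(v_ce, p.v_max, p.kappa, p.N_ecc)


def ce_force(A: float, l_ce: float, v_ce: float, p: MuscleParams) -> float:
    """Contractile-element force ``A F_max fl(l) fv(v)``, N."""
    if not 0.0 <= A <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    return A * p.F_max * force_length(l_ce, p) * force_velocity(v_ce, p)


def muscle_lengths(phi_h: float, p_rf: MuscleParams,
                   p_ham: MuscleParams) -> tuple[float, float]:
    """(L_RF, L_HAM) at hip angle ``phi_h``: RF lengthens with hip
    extension (increasing ``phi_h``), HAM shortens."""
    L_rf = p_rf.L_mtu0 + p_rf.rho * p_rf.r0 * (phi_h - p_rf.phi_ref)
    L_ham = p_ham.L_mtu0 + p_ham.rho * p_ham.r0 * (p_ham.phi_ref - phi_h)
    if L_rf <= 0 or L_ham <= 0:
        raise ValueError("non-positive muscle length: geometry misconfigured")
    return L_rf, L_ham


def muscle_velocities(phidot_h: float, p_rf: MuscleParams,
                      p_ham: MuscleParams) -> tuple[float, float]:
    """(v_RF, v_HAM) in m/s, the time derivatives of the lengths."""
    return (p_rf.rho * p_rf.r0 * phidot_h,
            -p_ham.rho * p_ham.r0 * phidot_h)


def hip_torque(F_rf: float, F_ham: float, r0: float) -> float:
    """Net hip torque on the trunk ``(F_HAM - F_RF) r0``; the hamstrings
    rotate the trunk backward (positive), the rectus femoris forward."""
    if F_rf < 0 or F_ham < 0:
        raise ValueError("muscle forces must be non-negative")
    return (F_ham - F_rf) * r0


def stimulation(F_s_delayed: float, gain: float, stim0: float,
                bounds: tuple[float, float] = (0.0, 1.0)) -> float:
    """Saturated affine reflex map ``Sat(STIM0 + G * Fs(t - delta_p))``."""
    return _core.sat(stim0 + gain * F_s_delayed, bounds[0], bounds[1])


def activation_derivative(A: float, stim: float, T: float) -> float:
    """First-order excitation-contraction lag ``dA/dt = (stim - A)/T``."""
    if T <= 0:
        raise ValueError("ECC time constant must be positive")
    return (stim - A) / T


class ForceHistory:
    """Append-only record of (t, Fs) samples with delayed linear-interp
    lookup; the reflex pathway reads the leg force ``delta_p`` in the past.

    Times must be appended in non-decreasing order.  Queries before the
    first sample return 0 (no force before the record starts).
    """

    def __init__(self) -> None:
        self._t: list[float] = []
        self._f: list[float] = []

    def append(self, t: float, f: float) -> None:
        if self._t and t < self._t[-1]:
            raise ValueError("history times must be non-decreasing")
        self._t.append(float(t))
        self._f.append(float(f))

    def __len__(self) -> int:
        return len(self._t)

    def value_at(self, t: float) -> float:
        if not self._t or t < self._t[0]:
            return 0.0
        if t >= self._t[-1]:
            return self._f[-1]
        i = bisect_right(self._t, t)
        t0, t1 = self._t[i - 1], self._t[i]
        if t1 <= t0:
            return self._f[i]
        w = (t - t0) / (t1 - t0)
        return self._f[i - 1] * (1.0 - w) + self._f[i] * w


def delayed_leg_force(history: ForceHistory, t: float,
                      delta_p: float) -> float:
    """Leg axial force ``delta_p`` seconds before ``t``; 0 before the
    simulation start and for legs with no recorded loading."""
    return history.value_at(t - delta_p)
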