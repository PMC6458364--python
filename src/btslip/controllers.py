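"""Balance controllers and the step-to-step (Poincare) control layer.

Four balance strategies share the same walking engine:

* ``fmch``          -- force-modulated compliant hip: tau = G Fs (phi_h0 - phi_h)
* ``nmf``           -- neuromuscular FMCH: delayed leg-force reflex drives the
                       RF/HAM Hill muscles
* ``preflex``       -- feed-forward replay of recorded steady nmF activations
* ``adaptive_nmf``  -- nmF plus a discrete LQR that retunes the two reflex
                       gains once per step at mid-stance

Swing-leg placement is velocity-based leg adjustment (VBLA) in all cases.

The LQR layer works on the mid-stance Poincare map ``S_{k+1} = F(S_k, U_k)``
with state ``S = (vx, y, vy, phi, phidot)`` and input ``U = (G_HAM, G_RF)``.
``linearize`` builds the Jacobians by central differences, ``solve_dlqr``
iterates the discrete Riccati recursion, and ``adapt_gains`` applies
``U_k = U* - K (S_k - S*)`` with a non-negativity floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import _core
from .engine import Simulator
from .params import FMCHParams, WalkerParams

__all__ = [
    "FallError",
    "ControlGains",
    "vbla_direction",
    "fmch_torque",
    "nmf_torque",
    "ZeroController",
    "FMCHController",
    "NMFController",
    "PreflexController",
    "AdaptiveNMFController",
    "PreflexLibrary",
    "make_controller",
    "StepToStepMap",
    "poincare_map",
    "linearize",
    "solve_dlqr",
    "adapt_gains",
    "NMF_GAINS_CALIBRATED",
]

#: Reflex gain pair (G_RF, G_HAM) in 1/N used for gait studies: output of
#: analysis.calibrate_nmf_gains.  The trunk-torque/hip-work balance of the
#: 1 m/s cycle pins the HAM:RF ratio; among the gain magnitudes that close
#: the cycle, this one recovers fastest from the standard trunk push.
NMF_GAINS_CALIBRATED = (1.0e-3, 1.3672137195018341e-3)


class FallError(RuntimeError):
    """The walker fell (or the step never completed) inside a map
    evaluation; distinct from numerical failure."""

    def __init__(self, reason: str, t: float):
        super().__init__(f"walker failed during step map: {reason} at t={t:.3f}")
        self.reason = reason
        self.t = t


@dataclass(frozen=True)
class ControlGains:
    """Reflex gain vector in the LQR's ordering U = (G_HAM, G_RF), 1/N."""

    G_HAM: float
    G_RF: float

    def __post_init__(self):
        if self.G_HAM < 0 or self.G_RF < 0:
            raise ValueError("reflex gains must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.G_HAM, self.G_RF])

    @classmethod
    def from_array(cls, u) -> "ControlGains":
        return cls(G_HAM=float(u[0]), G_RF=float(u[1]))


def _u_to_kernel(u) -> np.ndarray:
    """LQR order (G_HAM, G_RF) -> kernel order (G_RF, G_HAM)."""
    return np.array([u[1], u[0]], dtype=float)


# ---------------------------------------------------------------------------
# torque laws and leg placement
# ---------------------------------------------------------------------------

def vbla_direction(V, mu: float, g: float = 9.81) -> np.ndarray:
    """Velocity-based leg adjustment: unit swing-leg direction from the
    weighted sum of the CoM velocity and the gravity vector (magnitude g).

    ``mu = 0`` aligns the leg with the velocity, ``mu = 1`` points it
    straight down.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    o = np.array([(1.0 - mu) * V[0], (1.0 - mu) * V[1] - mu * g])
    n = np.linalg.norm(o)
    if n == 0.0:
        raise ValueError("VBLA direction undefined for zero weighted sum")
    return o / n


def fmch_torque(F_s: float, phi_h: float, p: FMCHParams) -> float:
    """Force-modulated rotational spring: tau = G Fs (phi_h0 - phi_h)."""
    if F_s < 0:
        raise ValueError("leg force must be non-negative")
    return p.G * F_s * (p.phi_h0 - phi_h)


def nmf_torque(state, leg: int, params: WalkerParams) -> float:
    """Hip torque of one stance leg from its current muscle activations.

    The activations live in the walker state (they are advanced by the
    engine as part of the global ODE); this composes geometry ->
    force-length/velocity -> CE forces -> torque.
    """
    from .mechanics import hip_angle, hip_angle_rate
    from .muscle import muscle_lengths, muscle_velocities, hip_torque

    foot = (state.foot_x[leg], 0.0)
    phi_h = hip_angle(state, foot, params.model)
    phidot_h = hip_angle_rate(state, foot, params.model)
    L_rf, L_ham = muscle_lengths(phi_h, params.rf, params.ham)
    v_rf, v_ham = muscle_velocities(phidot_h, params.rf, params.ham)
    a_rf = float(state.activations[2 * leg])
    a_ham = float(state.activations[2 * leg + 1])
    # fl/fv evaluated with v and v_max both in m/s (the ratio is unit-free)
    F_rf = a_rf * params.rf.F_max \
        * _core.fl_curve(L_rf, params.rf.l_opt, params.rf.w, params.rf.c) \
        * _core.fv_curve(v_rf, params.rf.v_max_mps, params.rf.kappa, params.rf.N_ecc)
    F_ham = a_ham * params.ham.F_max \
        * _core.fl_curve(L_ham, params.ham.l_opt, params.ham.w, params.ham.c) \
        * _core.fv_curve(v_ham, params.ham.v_max_mps, params.ham.kappa, params.ham.N_ecc)
    return hip_torque(F_rf, F_ham, params.rf.r0)


# ---------------------------------------------------------------------------
# controller objects (consumed by engine.Simulator)
# ---------------------------------------------------------------------------

class ZeroController:
    """No hip torque: the passive walker (falls; used for tests)."""

    kernel_id = _core.CTRL_ZERO
    gains = np.zeros(2)
    preflex_tables = None


class FMCHController:
    """Force-modulated compliant hip with fixed (G, phi_h0)."""

    kernel_id = _core.CTRL_FMCH
    preflex_tables = None

    def __init__(self, params: Optional[FMCHParams] = None):
        self.params = params or FMCHParams()
        self.gains = np.zeros(2)


class NMFController:
    """Leg-force reflex onto the RF/HAM pair (neuromuscular FMCH)."""

    kernel_id = _core.CTRL_NMF
    preflex_tables = None

    def __init__(self, gains=NMF_GAINS_CALIBRATED):
        # kernel order (G_RF, G_HAM)
        self.gains = np.asarray(gains, dtype=float)


@dataclass
class PreflexLibrary:
    """Per-leg activation traces vs time since that leg's touchdown,
    recorded from a converged nmF limit cycle, plus the timing metadata
    needed to start a replay at mid-stance."""

    t: np.ndarray
    a_rf: np.ndarray
    a_ham: np.ndarray
    stride_duration: float
    step_duration: float
    midstance_offset: float  # time from a leg's touchdown to its mid-stance

    def __post_init__(self):
        if len(self.t) < 2:
            raise ValueError("preflex library needs at least two samples")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_since_touchdown": self.t, "A_RF": self.a_rf,
                      "A_HAM": self.a_ham}).to_csv(path, index=False)
        meta = Path(path).with_suffix(".meta.csv")
        pd.DataFrame([{"stride_duration": self.stride_duration,
                       "step_duration": self.step_duration,
                       "midstance_offset": self.midstance_offset}]
                     ).to_csv(meta, index=False)

    @classmethod
    def from_csv(cls, path) -> "PreflexLibrary":
        df = pd.read_csv(path)
        meta = pd.read_csv(Path(path).with_suffix(".meta.csv")).iloc[0]
        return cls(t=df["time_since_touchdown"].to_numpy(),
                   a_rf=df["A_RF"].to_numpy(), a_ham=df["A_HAM"].to_numpy(),
                   stride_duration=float(meta["stride_duration"]),
                   step_duration=float(meta["step_duration"]),
                   midstance_offset=float(meta["midstance_offset"]))

    @classmethod
    def from_result(cls, result, leg: Optional[int] = None,
                    stride_index: int = 6) -> "PreflexLibrary":
        """Extract one leg's activation trace over one stride of a recorded
        (converged) nmF run."""
        tds = [e for e in result.events if e.kind == "touchdown"]
        if len(tds) < stride_index + 3:
            raise ValueError("run too short to extract a preflex stride")
        e0, e2 = tds[stride_index], tds[stride_index + 2]
        if leg is None:
            leg = e0.leg
        if e2.leg != leg:
            e2 = tds[stride_index + 1]
        traj = result.trajectory
        w = traj[(traj["t"] >= e0.t) & (traj["t"] <= e2.t)]
        if not len(w):
            raise ValueError("no trajectory recorded over the stride")
        mids = [e for e in result.events
                if e.kind == "midstance" and e0.t < e.t < e2.t and e.leg == leg]
        if not mids:
            raise ValueError("no mid-stance of the recorded leg in the stride")
        e1 = tds[stride_index + 1]
        return cls(t=w["t"].to_numpy() - e0.t,
                   a_rf=w[f"A_rf_{leg}"].to_numpy(),
                   a_ham=w[f"A_ham_{leg}"].to_numpy(),
                   stride_duration=e2.t - e0.t,
                   step_duration=e1.t - e0.t,
                   midstance_offset=mids[0].t - e0.t)

    def activations_at(self, clock: float) -> tuple[float, float]:
        """Replay values at a given time since touchdown (end values held)."""
        a_rf = _core.table_interp(self.t, self.a_rf, clock)
        a_ham = _core.table_interp(self.t, self.a_ham, clock)
        return a_rf, a_ham

    def td_offsets_at_midstance(self) -> tuple[float, float]:
        """(stance clock, swing clock) when a replay starts at mid-stance."""
        swing = self.midstance_offset + self.stride_duration - self.step_duration
        return self.midstance_offset, swing


class PreflexController:
    """Open-loop replay of the recorded steady-gait activations; no
    sensory feedback at all (the muscles' intrinsic properties are the
    only 'control')."""

    kernel_id = _core.CTRL_PREFLEX
    gains = np.zeros(2)

    def __init__(self, library: PreflexLibrary):
        if library is None:
            raise ValueError("preflex control requires a recorded library")
        self.library = library
        self.preflex_tables = (library.t, library.a_rf, library.a_ham)


class AdaptiveNMFController(NMFController):
    """nmF with once-per-step LQR retuning of the reflex gain pair.

    At every mid-stance crossing the deviation of the sampled Poincare
    state from the reference fixed point is fed back through the LQR gain:
    ``U_k = U* - K (S_k - S*)``, clamped at ``gain_floor``; the adapted
    gains persist until the next mid-stance.
    """

    def __init__(self, K: np.ndarray, S_star: np.ndarray,
                 U_star=None, gain_floor: float = 0.0):
        if U_star is None:
            g_rf, g_ham = NMF_GAINS_CALIBRATED
            U_star = np.array([g_ham, g_rf])
        self.K = np.asarray(K, dtype=float)
        self.S_star = np.asarray(S_star, dtype=float)
        self.U_star = np.asarray(U_star, dtype=float)
        self.gain_floor = gain_floor
        self.gain_log: list[tuple[float, float, float]] = []  # (t, G_HAM, G_RF)
        super().__init__(gains=_u_to_kernel(self.U_star))

    def on_midstance(self, sim: Simulator, t: float, S: np.ndarray) -> None:
        U_k = adapt_gains(S, self.S_star, self.U_star, self.K, self.gain_floor)
        sim.gains[:] = _u_to_kernel(U_k)
        self.gain_log.append((t, float(U_k[0]), float(U_k[1])))


def make_controller(kind: str, params: WalkerParams, *,
                    gains=None, library: Optional[PreflexLibrary] = None,
                    K=None, S_star=None, U_star=None,
                    gain_floor: float = 0.0):
    """Factory for the four balance strategies (plus 'zero' for tests)."""
    kind = kind.lower()
    if kind == "zero":
        return ZeroController()
    if kind == "fmch":
        return FMCHController(params.fmch)
    if kind == "nmf":
        return NMFController(gains if gains is not None else NMF_GAINS_CALIBRATED)
    if kind == "preflex":
        return PreflexController(library)
    if kind == "adaptive_nmf":
        if K is None or S_star is None:
            raise ValueError("adaptive nmF needs an LQR gain K and S_star")
        return AdaptiveNMFController(K, S_star, U_star, gain_floor)
    raise ValueError(f"unknown controller kind {kind!r}")


# ---------------------------------------------------------------------------
# Poincare map and LQR design
# ---------------------------------------------------------------------------

class StepToStepMap:
    """The mid-stance Poincare map ``S_{k+1} = F(S_k, U_k)``.

    Reconstructs a full walker state from the 5-vector ``S`` (stance leg
    vertical, activations quasi-steady), simulates exactly one step
    (touchdown, takeoff, next mid-stance) and returns the sampled
    5-vector.  A fall or a malformed event sequence raises
    :class:`FallError`; numerical failure raises ``ArithmeticError``.
    """

    def __init__(self, params: WalkerParams, kind: str = "nmf",
                 library: Optional[PreflexLibrary] = None,
                 h: float = 2.5e-4, t_max_step: float = 5.0):
        self.params = params
        self.kind = kind
        self.library = library
        self.h = h
        self.t_max_step = t_max_step
        self.last_step_time: float = math.nan
        self.last_step_length: float = math.nan

    def _controller(self, U):
        if self.kind == "nmf":
            gains = NMF_GAINS_CALIBRATED if U is None else _u_to_kernel(U)
            return NMFController(gains)
        if self.kind == "fmch":
            return FMCHController(self.params.fmch)
        if self.kind == "preflex":
            return PreflexController(self.library)
        raise ValueError(f"step map undefined for controller {self.kind!r}")

    def __call__(self, S, U=None) -> np.ndarray:
        sim = Simulator(self.params, self._controller(U), h=self.h,
                        record=False)
        offsets = (0.0, 0.0)
        if self.kind == "preflex":
            offsets = self.library.td_offsets_at_midstance()
        sim.init_midstance(S, td_offsets=offsets)
        x0 = sim.y[0]
        seen_td = seen_to = False
        while True:
            ev = sim.advance(self.t_max_step)
            if ev.kind == "touchdown":
                if seen_td:
                    raise FallError("second touchdown before mid-stance", ev.t)
                seen_td = True
            elif ev.kind == "takeoff":
                seen_to = True
            elif ev.kind == "midstance":
                if seen_td and seen_to:
                    self.last_step_time = sim.t
                    self.last_step_length = sim.y[0] - x0
                    return sim.poincare_vector()
                raise FallError("mid-stance before a complete step", ev.t)
            elif ev.kind == "numerical":
                raise ArithmeticError("integrator produced non-finite state")
            else:
                raise FallError(ev.kind, ev.t)

    def step_speed(self) -> float:
        """Mean forward speed of the most recent successful step."""
        return self.last_step_length / self.last_step_time


def poincare_map(S, U, ctx: StepToStepMap) -> np.ndarray:
    """Functional form of :class:`StepToStepMap`: one application of the
    mid-stance return map with reflex gains ``U = (G_HAM, G_RF)``."""
    return ctx(S, U)


def linearize(pmap: Callable, S_star, U_star, h_rel: float = 1e-4,
              max_shrink: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference Jacobians (A_s, B_s) of the step map at a fixed
    point.

    State steps are ``h_rel`` times the characteristic scales (1 m/s, 1 m,
    1 rad, 1 rad/s -> all unity); input steps are relative to each gain's
    magnitude.  If a perturbed evaluation falls, the step is halved up to
    ``max_shrink`` times before giving up.
    """
    S_star = np.asarray(S_star, float)
    U_star = np.asarray(U_star, float)

    def column(fun, x0, j, h):
        for _ in range(max_shrink + 1):
            e = np.zeros_like(x0)
            e[j] = h
            try:
                return (np.asarray(fun(x0 + e)) - np.asarray(fun(x0 - e))) \
                    / (2.0 * h)
            except FallError:
                h *= 0.5
        raise FallError(f"perturbed simulation keeps falling (column {j})", 0.0)

    A = np.column_stack([column(lambda S: pmap(S, U_star), S_star, j, h_rel)
                         for j in range(5)])
    B = np.column_stack([
        column(lambda U: pmap(S_star, U), U_star, j,
               h_rel * max(abs(U_star[j]), 1e-6))
        for j in range(len(U_star))])
    return A, B


def solve_dlqr(A_s, B_s, Q, R, tol: float = 1e-10,
               max_iter: int = 100_000) -> tuple[np.ndarray, np.ndarray]:
    """Discrete LQR via fixed-point iteration of the Riccati recursion
    ``P <- Q + A'(P - P B (B'PB + R)^{-1} B'P) A`` from ``P0 = Q``;
    returns the feedback gain ``K = (B'PB + R)^{-1} B'PA`` and ``P``."""
    A = np.asarray(A_s, float)
    B = np.asarray(B_s, float)
    Q = np.asarray(Q, float)
    R = np.asarray(R, float)
    if np.any(np.linalg.eigvalsh((R + R.T) / 2) <= 0):
        raise ValueError("R must be positive definite")
    P = Q.copy()
    for _ in range(max_iter):
        BtP = B.T @ P
        gain = np.linalg.solve(BtP @ B + R, BtP)
        P_next = Q + A.T @ (P - P @ B @ gain) @ A
        if np.max(np.abs(P_next - P)) < tol:
            P = P_next
            break
        P = P_next
    else:
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        raise RuntimeError(
            f"Riccati iteration did not converge in {max_iter} steps "
            f"(spectral radius of A_s is {rho:.4f})")
    BtP = B.T @ P
    K = np.linalg.solve(BtP @ B + R, BtP @ A)
    return K, P


def adapt_gains(S_k, S_star, U_star, K, gain_floor: float = 0.0) -> np.ndarray:
    """Once-per-step gain update ``U_k = U* - K (S_k - S*)``, clamped below
    at ``gain_floor`` (muscle force feedback cannot be negative)."""
    U_k = np.asarray(U_star, float) - np.asarray(K, float) @ (
        np.asarray(S_k, float) - np.asarray(S_star, float))
    return np.maximum(U_k, gain_floor)
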