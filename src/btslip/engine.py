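"""Hybrid walking simulation: phase sequencing, events, verdicts, metrics.

The :class:`Simulator` advances the walker through alternating single- and
double-support phases.  Continuous dynamics run in the compiled kernel
(:mod:`btslip._core`); this module owns the discrete side: placing the swing
foot at touchdown, removing the rear leg at takeoff, sampling the mid-stance
Poincare section, injecting perturbations, and assembling the
:class:`SimResult` (trajectory, event log, stride summaries, stability
verdict).

Stability follows the step-to-fall convention: a run is *stable at a target
speed* if it completes the requested number of steps and every per-step mean
forward speed stays within 5% of the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _core
from ._core import (EV_FALL, EV_MIDSTANCE, EV_NAN, EV_TAKEOFF, EV_TMAX,
                    EV_TOUCHDOWN, PH_DOUBLE, PH_SINGLE)
from .params import WalkerParams

__all__ = [
    "WalkerState",
    "EventRecord",
    "PerturbationSpec",
    "SimResult",
    "Simulator",
    "pack_params",
    "apply_perturbation",
    "stride_energy",
    "recovery_time",
    "SPEED_TOL",
]

#: per-step speed tolerance of the stability definition (fraction of target)
SPEED_TOL = 0.05

_EVENT_NAMES = {EV_TOUCHDOWN: "touchdown", EV_TAKEOFF: "takeoff",
                EV_MIDSTANCE: "midstance", EV_FALL: "fall",
                EV_TMAX: "tmax", EV_NAN: "numerical"}
_FALL_REASONS = {_core.FALL_UNLOADED: "leg_unloaded",
                 _core.FALL_LOW_HIP: "hip_too_low",
                 _core.FALL_PITCH: "trunk_pitch"}

_TRAJ_COLS = ["t", "x", "y", "vx", "vy", "phi", "phidot",
              "A_rf_0", "A_ham_0", "A_rf_1", "A_ham_1",
              "tau_0", "tau_1", "grf_x_0", "grf_y_0", "grf_x_1", "grf_y_1",
              "Fs_0", "Fs_1", "phi_h_0", "phi_h_1",
              "phidot_h_0", "phidot_h_1", "contact_0", "contact_1",
              "foot_x_0", "foot_x_1"]


@dataclass
class WalkerState:
    """Continuous mechanical state plus muscle activations and contacts."""

    x: float
    y: float
    vx: float
    vy: float
    phi: float
    phidot: float
    activations: np.ndarray = field(
        default_factory=lambda: np.zeros(4))  # RF0, HAM0, RF1, HAM1
    foot_x: np.ndarray = field(default_factory=lambda: np.zeros(2))
    contact: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    phase: int = PH_SINGLE
    stance_leg: int = 0

    def as_vector(self) -> np.ndarray:
        v = np.empty(10)
        v[:6] = (self.x, self.y, self.vx, self.vy, self.phi, self.phidot)
        v[6:] = self.activations
        return v


@dataclass
class EventRecord:
    kind: str
    t: float
    leg: int
    state: np.ndarray


@dataclass
class PerturbationSpec:
    """Instantaneous state modification at a touchdown event.

    ``stride`` counts non-overlapping strides of the leg that touches down
    first: stride *n* opens at the ``2n - 1``-th touchdown of the run (the
    run starts at mid-stance, mid-stride)."""

    kind: str = "set_phidot"           # set_phidot | add_phidot | set_phi
    magnitude: float = math.radians(-50.0)
    stride: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("set_phidot", "add_phidot", "set_phi"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    @property
    def trigger_touchdown(self) -> int:
        return 2 * self.stride - 1


def apply_perturbation(y: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Apply ``spec`` to a 10-element state vector (returns a copy)."""
    out = y.copy()
    if spec.kind == "set_phidot":
        out[5] = spec.magnitude
    elif spec.kind == "add_phidot":
        out[5] += spec.magnitude
    else:
        out[4] = spec.magnitude
    return out


@dataclass
class SimResult:
    """Outcome of one walking simulation."""

    trajectory: pd.DataFrame
    events: list
    steps: pd.DataFrame
    strides: pd.DataFrame
    stable: bool
    failure_reason: Optional[str]
    n_steps_completed: int
    t_end: float
    speed_target: float
    perturbation_time: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    @property
    def mean_speed(self) -> float:
        return float(self.steps["speed"].mean()) if len(self.steps) else math.nan


def pack_params(params: WalkerParams, h: float = 2.5e-4,
                fall_y: float = 0.2,
                fall_phi: float = math.pi / 3.0) -> np.ndarray:
    """Flatten a :class:`WalkerParams` into the kernel parameter vector.

    Muscle constants other than the reference angle are taken from the RF
    bundle (the published set uses identical values for both groups)."""
    m, rf, ham, rx, fm = (params.model, params.rf, params.ham,
                          params.reflex, params.fmch)
    P = np.zeros(_core.NPAR)
    P[_core.IM] = m.m
    P[_core.IJ] = m.J_trunk
    P[_core.IRH] = m.r_h
    P[_core.IL0] = m.l0
    P[_core.IG] = m.g
    P[_core.IK] = m.k
    P[_core.IMU] = m.mu_vbla
    P[_core.IFMAX] = rf.F_max
    P[_core.ILOPT] = rf.l_opt
    P[_core.IVMAX] = rf.v_max_mps
    P[_core.IW] = rf.w
    P[_core.IC] = rf.c
    P[_core.INECC] = rf.N_ecc
    P[_core.IKAP] = rf.kappa
    P[_core.IRHO] = rf.rho
    P[_core.IR0] = rf.r0
    P[_core.ILMTU0] = rf.L_mtu0
    P[_core.IPREF_RF] = rf.phi_ref
    P[_core.IPREF_HAM] = ham.phi_ref
    P[_core.ISTIM0] = rx.STIM0
    P[_core.IDELTAP] = rx.delta_p
    P[_core.ITECC] = rx.T_ecc
    P[_core.ISTIMLO] = rx.stim_lo
    P[_core.ISTIMHI] = rx.stim_hi
    P[_core.IGFMCH] = fm.G
    P[_core.IPHIH0] = fm.phi_h0
    P[_core.IH] = min(h, rx.delta_p) if rx.delta_p > 0 else h
    P[_core.IFALLY] = fall_y
    P[_core.IFALLPHI] = fall_phi
    return P


_EMPTY = np.empty(0)


class Simulator:
    """Stateful hybrid integrator for one walker + controller pair.

    The controller object supplies ``kernel_id`` (one of the ``CTRL_*``
    constants), a ``gains`` array (G_RF, G_HAM) for reflex controllers,
    optional preflex replay tables, and an optional ``on_midstance`` hook
    called with ``(sim, t, S)`` at every mid-stance crossing (this is where
    once-per-step gain adaptation lives).
    """

    def __init__(self, params: WalkerParams, controller, h: float = 2.5e-4,
                 record: bool = True, rec_every: int = 4,
                 hist_len: int = 256):
        self.params = params
        self.controller = controller
        self.P = pack_params(params, h=h)
        self.h = self.P[_core.IH]
        self.rec_every = rec_every
        self.record = record
        self.hist_len = hist_len
        self.gains = np.asarray(
            getattr(controller, "gains", np.zeros(2)), dtype=float).copy()
        pf = getattr(controller, "preflex_tables", None)
        if pf is None:
            self.pf_t, self.pf_rf, self.pf_ham = _EMPTY, _EMPTY, _EMPTY
        else:
            self.pf_t, self.pf_rf, self.pf_ham = (
                np.ascontiguousarray(a, dtype=float) for a in pf)
        self.reset()

    # -- state management -----------------------------------------------------

    def reset(self) -> None:
        self.t = 0.0
        self.y = np.zeros(10)
        self.feet = np.zeros(2)
        self.contact = np.zeros(2, dtype=np.int64)
        self.td_time = np.zeros(2)
        self.phase = PH_SINGLE
        self.stance = 0
        self.hist_t = np.zeros((2, self.hist_len))
        self.hist_F = np.zeros((2, self.hist_len))
        self.hist_n = np.zeros(2, dtype=np.int64)
        self._rec_t = _EMPTY
        self._rec_y = np.empty((0, 10))
        self._rec_aux = np.empty((0, _core.NAUX))
        self._rec_n = np.zeros(1, dtype=np.int64)

    def init_midstance(self, S, stance_leg: int = 0,
                       td_offsets=(0.0, 0.0)) -> None:
        """Reconstruct a full walker state from the 5-vector Poincare state
        ``S = (vx, y, vy, phi, phidot)`` at mid-stance (stance leg vertical).

        Activations start at their quasi-steady values (the excitation-
        contraction lag is three orders of magnitude faster than the stride,
        so they are slaved to the leg-force history), and the reflex delay
        buffer is pre-filled with the instantaneous stance force.
        ``td_offsets`` gives the time since each leg's last touchdown, used
        by replay controllers.
        """
        vx, yc, vy, phi, phid = (float(v) for v in S)
        self.reset()
        m = self.params.model
        rx = self.params.reflex
        xh = 0.0 - m.r_h * math.cos(phi)
        yh = yc - m.r_h * math.sin(phi)
        if yh <= 0:
            raise ValueError("hip below ground in mid-stance reconstruction")
        Fs = m.k * (m.l0 - yh)
        self.y[:6] = (0.0, yc, vx, vy, phi, phid)
        swing = 1 - stance_leg
        a_stance_rf = min(max(rx.STIM0 + self.gains[0] * max(Fs, 0.0),
                              rx.stim_lo), rx.stim_hi)
        a_stance_ham = min(max(rx.STIM0 + self.gains[1] * max(Fs, 0.0),
                               rx.stim_lo), rx.stim_hi)
        self.y[6 + 2 * stance_leg] = a_stance_rf
        self.y[7 + 2 * stance_leg] = a_stance_ham
        self.y[6 + 2 * swing] = rx.STIM0
        self.y[7 + 2 * swing] = rx.STIM0
        self.feet[stance_leg] = xh
        self.contact[stance_leg] = 1
        self.phase = PH_SINGLE
        self.stance = stance_leg
        self.td_time[stance_leg] = -float(td_offsets[0])
        self.td_time[swing] = -float(td_offsets[1])
        # pre-fill the delay buffer so the reflex sees the current force
        for leg, F in ((stance_leg, max(Fs, 0.0)), (swing, 0.0)):
            _core.hist_write(self.hist_t, self.hist_F, self.hist_n, leg,
                             -rx.delta_p - self.h, F)
            _core.hist_write(self.hist_t, self.hist_F, self.hist_n, leg,
                             0.0, F)

    def state(self) -> WalkerState:
        y = self.y
        return WalkerState(x=y[0], y=y[1], vx=y[2], vy=y[3], phi=y[4],
                           phidot=y[5], activations=y[6:].copy(),
                           foot_x=self.feet.copy(),
                           contact=self.contact.copy(),
                           phase=self.phase, stance_leg=self.stance)

    def poincare_vector(self) -> np.ndarray:
        """The 5-vector S = (vx, y, vy, phi, phidot)."""
        y = self.y
        return np.array([y[2], y[1], y[3], y[4], y[5]])

    # -- integration ----------------------------------------------------------

    def _alloc_recording(self, t_max: float) -> None:
        if not self.record:
            return
        n = int(t_max / (self.h * self.rec_every)) + 4096
        self._rec_t = np.empty(n)
        self._rec_y = np.empty((n, 10))
        self._rec_aux = np.empty((n, _core.NAUX))
        self._rec_n = np.zeros(1, dtype=np.int64)

    def advance(self, t_max: float) -> EventRecord:
        """Integrate to the next event (or ``t_max``) and apply the discrete
        transition; returns the event record (spec: one step of the hybrid
        event sequence)."""
        code, reason, t = _core.integrate_segment(
            self.t, self.y, self.phase, self.stance, self.feet, self.contact,
            self.td_time, self.P, self.gains, self.controller.kernel_id,
            self.hist_t, self.hist_F, self.hist_n,
            self.pf_t, self.pf_rf, self.pf_ham,
            t_max, self.rec_every,
            self._rec_t, self._rec_y, self._rec_aux, self._rec_n)
        self.t = t
        leg = -1
        if code == EV_TOUCHDOWN:
            leg = 1 - self.stance
            self._place_foot(leg)
            self.td_time[leg] = t
            self.phase = PH_DOUBLE  # self.stance stays = rear leg
        elif code == EV_TAKEOFF:
            leg = self.stance
            self.contact[leg] = 0
            self.phase = PH_SINGLE
            self.stance = 1 - leg
        elif code == EV_MIDSTANCE:
            leg = self.stance
            hook = getattr(self.controller, "on_midstance", None)
            if hook is not None:
                hook(self, t, self.poincare_vector())
        elif code == EV_FALL:
            kind = "fall"
            return EventRecord(kind=f"fall:{_FALL_REASONS[reason]}", t=t,
                               leg=self.stance, state=self.y.copy())
        return EventRecord(kind=_EVENT_NAMES[code], t=t, leg=leg,
                           state=self.y.copy())

    def _place_foot(self, leg: int) -> None:
        m = self.params.model
        y = self.y
        xh = y[0] - m.r_h * math.cos(y[4])
        yh = y[1] - m.r_h * math.sin(y[4])
        ox, oy = _core.vbla(y[2], y[3], m.mu_vbla, m.g)
        dx = math.sqrt(max(m.l0 ** 2 - yh ** 2, 0.0))
        self.feet[leg] = xh + math.copysign(dx, ox)
        self.contact[leg] = 1

    def run(self, n_steps: int = 50, speed_target: float = 1.0,
            t_max: Optional[float] = None,
            perturbation: Optional[PerturbationSpec] = None,
            speed_tol: float = SPEED_TOL) -> SimResult:
        """Walk up to ``n_steps`` touchdowns and judge stability.

        The verdict is ``True`` iff all steps completed and every per-step
        mean forward speed (touchdown to touchdown) lies within
        ``speed_tol`` of ``speed_target``.
        """
        if t_max is None:
            t_max = 2.0 * n_steps + 10.0
        self._alloc_recording(t_max)
        events: list[EventRecord] = []
        touchdowns: list[tuple[float, float]] = []
        perturbation_time = None
        failure = None
        while True:
            ev = self.advance(t_max)
            events.append(ev)
            if ev.kind == "touchdown":
                touchdowns.append((ev.t, self.y[0]))
                ntd = len(touchdowns)
                if (perturbation is not None and perturbation_time is None
                        and ntd >= perturbation.trigger_touchdown):
                    self.y = apply_perturbation(self.y, perturbation)
                    perturbation_time = ev.t
                if ntd >= n_steps:
                    break
            elif ev.kind.startswith("fall"):
                failure = ev.kind
                break
            elif ev.kind in ("tmax", "numerical"):
                failure = ev.kind if ev.kind == "numerical" else "timeout"
                break
        return self._build_result(events, touchdowns, n_steps, speed_target,
                                  speed_tol, failure, perturbation_time)

    # -- result assembly ------------------------------------------------------

    def _build_result(self, events, touchdowns, n_steps, speed_target,
                      speed_tol, failure, perturbation_time) -> SimResult:
        traj = self._trajectory_frame()
        steps = _step_table(touchdowns)
        strides = _stride_table(touchdowns, events, traj)
        ok_steps = len(touchdowns) >= n_steps
        ok_speed = bool(len(steps)) and bool(
            (np.abs(steps["speed"] - speed_target)
             <= speed_tol * speed_target).all())
        stable = failure is None and ok_steps and ok_speed
        if failure is None and ok_steps and not ok_speed:
            failure = "speed_out_of_band"
        return SimResult(trajectory=traj, events=events, steps=steps,
                         strides=strides, stable=stable,
                         failure_reason=failure,
                         n_steps_completed=len(touchdowns), t_end=self.t,
                         speed_target=speed_target,
                         perturbation_time=perturbation_time,
                         metadata={"controller": type(self.controller).__name__,
                                   "h": self.h})

    def _trajectory_frame(self) -> pd.DataFrame:
        n = int(self._rec_n[0])
        if n == 0:
            return pd.DataFrame(columns=_TRAJ_COLS)
        data = np.empty((n, len(_TRAJ_COLS)))
        data[:, 0] = self._rec_t[:n]
        data[:, 1:11] = self._rec_y[:n]
        data[:, 11:] = self._rec_aux[:n]
        return pd.DataFrame(data, columns=_TRAJ_COLS)


def _step_table(touchdowns) -> pd.DataFrame:
    rows = []
    for i in range(1, len(touchdowns)):
        (t0, x0), (t1, x1) = touchdowns[i - 1], touchdowns[i]
        rows.append((i, t0, t1, t1 - t0, (x1 - x0) / (t1 - t0)))
    return pd.DataFrame(rows, columns=["step", "t_start", "t_end",
                                       "duration", "speed"])


def _stride_table(touchdowns, events, traj: pd.DataFrame) -> pd.DataFrame:
    """Per-stride summaries; a stride spans ipsilateral touchdowns
    (touchdown 2k-2 to touchdown 2k, non-overlapping)."""
    rows = []
    td_events = [e for e in events if e.kind == "touchdown"]
    to_events = [e for e in events if e.kind == "takeoff"]
    for i in range(0, len(touchdowns) - 2, 2):
        (t0, x0), (t1, x1) = touchdowns[i], touchdowns[i + 2]
        dur = t1 - t0
        energy = math.nan
        duty = math.nan
        if len(traj):
            window = traj[(traj["t"] >= t0) & (traj["t"] <= t1)]
            energy = stride_energy(window)
            leg = td_events[i].leg
            stance_end = next((e.t for e in to_events
                               if e.leg == leg and e.t > t0), None)
            if stance_end is not None:
                duty = min((stance_end - t0) / dur, 1.0)
        rows.append((i // 2 + 1, t0, t1, dur, (x1 - x0) / dur, energy, duty))
    return pd.DataFrame(rows, columns=["stride", "t_start", "t_end",
                                       "duration", "speed", "energy",
                                       "duty_factor"])


def stride_energy(traj: pd.DataFrame) -> float:
    """Hip energy over a trajectory slice: integral of the summed absolute
    hip powers |phidot_h1 tau1| + |phidot_h2 tau2| dt (joules)."""
    if len(traj) < 2:
        return 0.0
    t = traj["t"].to_numpy()
    p = np.zeros_like(t)
    for leg in range(2):
        tau = traj[f"tau_{leg}"].to_numpy()
        om = np.nan_to_num(traj[f"phidot_h_{leg}"].to_numpy())
        p = p + np.abs(om * tau)
    return float(np.trapezoid(p, t))


def peak_hip_power(traj: pd.DataFrame) -> float:
    """Maximum instantaneous summed absolute hip power, W."""
    if not len(traj):
        return 0.0
    p = np.zeros(len(traj))
    for leg in range(2):
        tau = traj[f"tau_{leg}"].to_numpy()
        om = np.nan_to_num(traj[f"phidot_h_{leg}"].to_numpy())
        p = p + np.abs(om * tau)
    return float(p.max())


def recovery_time(result: SimResult, band: float = math.radians(2.0),
                  settle_duration: Optional[float] = None) -> float:
    """Time after the perturbation for the trunk angle to re-enter (and stay
    inside, for one full stride) the +-``band`` envelope of the
    pre-perturbation trunk-angle pattern.

    The reference pattern is the last full stride before the perturbation in
    the same run.  Returns 0 for an unperturbed run and ``inf`` if the trace
    never settles.
    """
    if result.perturbation_time is None:
        return 0.0
    traj = result.trajectory
    tp = result.perturbation_time
    pre = result.strides[result.strides["t_end"] <= tp + 1e-9]
    if not len(pre):
        raise ValueError("no complete pre-perturbation stride to reference")
    ref = pre.iloc[-1]
    ref_phi = traj[(traj["t"] >= ref["t_start"])
                   & (traj["t"] <= ref["t_end"])]["phi"]
    lo, hi = ref_phi.min() - band, ref_phi.max() + band
    if settle_duration is None:
        settle_duration = float(ref["duration"])
    post = traj[traj["t"] >= tp]
    t = post["t"].to_numpy()
    phi = post["phi"].to_numpy()
    inside = (phi >= lo) & (phi <= hi)
    # earliest entry time followed by a full stride inside the envelope
    i = 0
    n = len(t)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j < n and inside[j]:
            j += 1
        if (j < n and t[j - 1] - t[i] >= settle_duration) or \
           (j == n and result.failure_reason is None
                and t[j - 1] - t[i] >= settle_duration):
            return float(t[i] - tp)
        i = j
    return math.inf
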