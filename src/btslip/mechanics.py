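"""Rigid-trunk / massless-spring-leg (BTSLIP) kinematics and dynamics.

The walker is a rigid trunk of mass ``m`` and inertia ``J`` whose hip point
sits a distance ``r_h`` below the centre of mass along the trunk axis.  Legs
are massless linear springs between the hip and ground-fixed feet; each
stance leg transmits its axial spring force plus the tangential force that
a hip torque induces at the foot lever.

All angles are measured from the horizontal ``+x`` axis; an upright trunk
has ``phi = pi/2``.  The hip angle ``phi_h`` (trunk-to-leg angle) is
computed with a quadrant-aware arctangent so it is continuous through
mid-stance and equals ``pi`` when a vertical leg is the downward
continuation of an upright trunk (the convention required by the muscle
reference angles ~3.25-3.29 rad).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core
from .params import ModelParams

__all__ = [
    "GRFVector",
    "hip_position",
    "leg_length",
    "leg_spring_force",
    "grf_leg",
    "dynamics_single",
    "dynamics_double",
    "hip_angle",
    "hip_angle_rate",
    "mechanical_energy",
]


@dataclass(frozen=True)
class GRFVector:
    """Ground reaction force of one stance leg, N."""

    fx: float
    fy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fx, self.fy])


def _xyphi(state) -> tuple[float, float, float]:
    """Accept a WalkerState-like object or an (x, y, phi) triple."""
    if hasattr(state, "phi"):
        return float(state.x), float(state.y), float(state.phi)
    x, y, phi = state
    return float(x), float(y), float(phi)


def hip_position(state, p: ModelParams) -> tuple[float, float]:
    """Hip point, a distance ``r_h`` below the CoM along the trunk axis."""
    x, y, phi = _xyphi(state)
    return _core.hip_xy(x, y, phi, p.r_h)


def leg_length(hip, foot) -> float:
    """Euclidean hip-to-foot distance, m."""
    return math.hypot(hip[0] - foot[0], hip[1] - foot[1])


def leg_spring_force(l: float, p: ModelParams) -> float:
    """Axial leg-spring force ``k (l0 - l)``, repulsive positive.

    Negative values (overextension) are never transmitted in practice
    because takeoff fires at GRF_y = 0; they signal an unloading leg.
    """
    if l <= 0:
        raise ValueError("leg length must be positive")
    return p.k * (p.l0 - l)


def grf_leg(state, torque: float, foot, p: ModelParams) -> GRFVector:
    """Ground reaction force of one stance leg from its spring force and
    hip torque, in the world frame."""
    xh, yh = hip_position(state, p)
    l = leg_length((xh, yh), foot)
    if l <= 0:
        raise ValueError("degenerate leg of zero length")
    Fs = leg_spring_force(l, p)
    fx, fy = _core.grf_from(Fs, torque, xh, yh, foot[0])
    return GRFVector(fx, fy)


def _accels(state, grfs, torques, p: ModelParams):
    gx = sum(g.fx for g in grfs)
    gy = sum(g.fy for g in grfs)
    tau = sum(torques)
    phi = state.phi if hasattr(state, "phi") else state[2]
    ax = gx / p.m
    ay = gy / p.m - p.g
    alpha = (tau + p.r_h * (gx * math.sin(phi) - gy * math.cos(phi))) / p.J_trunk
    return ax, ay, alpha


def dynamics_single(state, torque: float, foot, p: ModelParams) -> np.ndarray:
    """Time derivative of the mechanical state in single support.

    Returns ``[vx, vy, ax, ay, phidot, phiddot]`` for a WalkerState-like
    input carrying velocities.
    """
    grf = grf_leg(state, torque, foot, p)
    ax, ay, alpha = _accels(state, (grf,), (torque,), p)
    return np.array([state.vx, state.vy, ax, ay, state.phidot, alpha])


def dynamics_double(state, torques, feet, p: ModelParams) -> np.ndarray:
    """Time derivative of the mechanical state in double support; sums the
    per-leg ground reaction forces and hip torques."""
    grfs = [grf_leg(state, tq, ft, p) for tq, ft in zip(torques, feet)]
    ax, ay, alpha = _accels(state, grfs, torques, p)
    return np.array([state.vx, state.vy, ax, ay, state.phidot, alpha])


def hip_angle(state, foot, p: ModelParams) -> float:
    """Trunk-to-leg angle ``phi_h``, continuous through mid-stance."""
    xh, yh = hip_position(state, p)
    if yh <= 0 and abs(xh - foot[0]) < 1e-12:
        raise ValueError("degenerate hip-on-ground configuration")
    return _core.hip_angle(_xyphi(state)[2], xh, yh, foot[0])


def hip_angle_rate(state, foot, p: ModelParams) -> float:
    """d(phi_h)/dt for a stationary foot."""
    xh, yh = hip_position(state, p)
    u = xh - foot[0]
    l2 = u * u + yh * yh
    ud = state.vx + p.r_h * math.sin(state.phi) * state.phidot
    vd = state.vy - p.r_h * math.cos(state.phi) * state.phidot
    return state.phidot - (u * vd - yh * ud) / l2


def mechanical_energy(state, feet, contact, p: ModelParams) -> float:
    """Kinetic + gravitational + leg-spring energy, J (diagnostic; conserved
    for torque-free smooth phases)."""
    x, y, phi = _xyphi(state)
    e = 0.5 * p.m * (state.vx ** 2 + state.vy ** 2) \
        + 0.5 * p.J_trunk * state.phidot ** 2 + p.m * p.g * y
    xh, yh = _core.hip_xy(x, y, phi, p.r_h)
    for leg in range(2):
        if contact[leg]:
            l = math.hypot(xh - feet[leg], yh)
            if l < p.l0:
                e += 0.5 * p.k * (p.l0 - l) ** 2
    return e
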