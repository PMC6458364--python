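"""Parameter bundles for the bipedal trunk-SLIP (BTSLIP) walker.

Defaults reproduce the published reference parameter set for a human-scale
walker: an 80 kg trunk on two massless prismatic spring legs (normalized leg
stiffness 40), actuated at the hip by a rectus femoris / hamstrings pair of
Hill-type muscles driven by delayed positive leg-force feedback.

All bundles are frozen dataclasses; derived quantities (dimensional leg
stiffness, muscle maximum shortening velocity in m/s) are exposed as
properties.  ``load_config``/``save_config`` round-trip the bundles through a
plain YAML file with one section per parameter table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "MuscleParams",
    "ReflexParams",
    "FMCHParams",
    "LQRConfig",
    "WalkerParams",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class ModelParams:
    """Mechanical parameters of the trunk + spring-leg model.

    ``k_N`` is the dimensionless leg stiffness; the dimensional spring
    constant is ``k = k_N * m * g / l0`` (standard SLIP normalization).
    """

    m: float = 80.0          # trunk mass, kg
    J_trunk: float = 4.6     # trunk moment of inertia, kg m^2
    r_h: float = 0.1         # hip-to-CoM distance, m
    l0: float = 1.0          # leg rest length, m
    g: float = 9.81          # gravitational acceleration, m/s^2
    k_N: float = 40.0        # normalized leg stiffness
    mu_vbla: float = 0.34    # velocity-based leg adjustment weighting

    def __post_init__(self) -> None:
        for name in ("m", "J_trunk", "r_h", "l0", "g", "k_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.mu_vbla <= 1.0:
            raise ValueError("mu_vbla must lie in [0, 1]")

    @property
    def k(self) -> float:
        """Dimensional leg spring stiffness, N/m."""
        return self.k_N * self.m * self.g / self.l0


@dataclass(frozen=True)
class MuscleParams:
    """Hill-type contractile-element parameters for one muscle group.

    The contractile element is the whole muscle-tendon unit here (no series
    elastic element), so the CE length is the geometric muscle length.
    ``v_max`` is expressed in optimal lengths per second and is negative
    (shortening) by convention.
    """

    name: str = "RF"
    L_mtu0: float = 0.11     # MTU reference length, m
    phi_ref: float = 3.291   # reference hip angle, rad
    r0: float = 0.1          # constant moment arm, m
    F_max: float = 2000.0    # maximum isometric force, N
    l_opt: float = 0.111     # optimal CE length, m
    v_max: float = -12.0     # maximum shortening velocity, l_opt/s (negative)
    w: float = 0.2           # force-length bell width, fraction of l_opt
    c: float = math.log(0.05)  # force-length shape constant (ln 0.05)
    N_ecc: float = 1.5       # eccentric force enhancement
    kappa: float = 5.0       # force-velocity curvature constant
    rho: float = 0.5         # pennation factor

    def __post_init__(self) -> None:
        if self.F_max <= 0 or self.l_opt <= 0 or self.w <= 0:
            raise ValueError("F_max, l_opt and w must be positive")
        if self.kappa <= 0 or self.N_ecc <= 1:
            raise ValueError("kappa must be > 0 and N_ecc > 1")
        if self.c >= 0:
            raise ValueError("force-length constant c must be negative")
        if self.v_max >= 0:
            raise ValueError("v_max is a shortening velocity and must be < 0")

    @property
    def v_max_mps(self) -> float:
        """Maximum shortening velocity in m/s (negative)."""
        return self.v_max * self.l_opt

    @property
    def sign(self) -> float:
        """dL/d(phi_h): +1 for muscles that lengthen with hip extension."""
        return 1.0 if self.name.upper() == "RF" else -1.0


def default_rf() -> MuscleParams:
    return MuscleParams(name="RF", phi_ref=3.291)


def default_ham() -> MuscleParams:
    return MuscleParams(name="HAM", phi_ref=3.246)


@dataclass(frozen=True)
class ReflexParams:
    """Leg-force reflex pathway: stimulation bias, gains, delay, ECC lag.

    Gains are in 1/N (they multiply the leg axial force); the published set
    is G_RF = 0.624/F_max and G_HAM = 0.936/F_max with F_max = 2000 N.
    """

    G_RF: float = 0.624 / 2000.0   # RF force-feedback gain, 1/N
    G_HAM: float = 0.936 / 2000.0  # HAM force-feedback gain, 1/N
    STIM0: float = 0.01            # stimulation bias
    delta_p: float = 1e-3          # feedback delay, s
    T_ecc: float = 1e-3            # excitation-contraction time constant, s
    stim_lo: float = 0.0
    stim_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.G_RF < 0 or self.G_HAM < 0:
            raise ValueError("reflex gains must be non-negative")
        if self.delta_p < 0:
            raise ValueError("feedback delay must be non-negative")
        if self.T_ecc <= 0:
            raise ValueError("T_ecc must be positive")


#: FMCH constants calibrated for a 1 m/s period-1 gait with the default
#: mechanics (see analysis.calibrate_fmch; values reproduced by the routine).
#: phi_h0 is the steady mid-stance hip angle (upright trunk over a vertical
#: leg); G sits mid-way in the spectrally stable stiffness window.
FMCH_G_DEFAULT = 0.5
FMCH_PHI_H0_DEFAULT = math.pi


@dataclass(frozen=True)
class FMCHParams:
    """Force-modulated compliant hip: tau = G * Fs * (phi_h0 - phi_h).

    ``G`` carries units of m/rad so that N * rad * (m/rad) = N m.  The
    published work gives the law but not the constants; the defaults here are
    the output of the package's deterministic calibration routine targeting a
    1 m/s period-1 gait.
    """

    G: float = FMCH_G_DEFAULT
    phi_h0: float = FMCH_PHI_H0_DEFAULT

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("FMCH gain must be non-negative")


@dataclass(frozen=True)
class LQRConfig:
    """Discrete-LQR design weights and Riccati iteration controls."""

    Q: np.ndarray = field(default_factory=lambda: np.eye(5))
    R: np.ndarray = field(default_factory=lambda: np.eye(2))
    tol: float = 1e-10
    max_iter: int = 100_000
    h_rel: float = 1e-4      # finite-difference step, relative to state scale
    gain_floor: float = 0.0  # adapted gains are clamped below at this value

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "R", R)
        if Q.shape != (5, 5) or R.shape != (2, 2):
            raise ValueError("Q must be 5x5 and R 2x2")
        if not (np.allclose(Q, Q.T) and np.allclose(R, R.T)):
            raise ValueError("Q and R must be symmetric")
        if np.any(np.linalg.eigvalsh(R) <= 0):
            raise ValueError("R must be positive definite")

    @classmethod
    def preset(cls, which: str) -> "LQRConfig":
        """The three published weighting cases: 'performance' (Q=100I),
        'balanced' (Q=R=I) and 'efficiency' (R=100I)."""
        presets = {
            "performance": (100.0, 1.0),
            "balanced": (1.0, 1.0),
            "efficiency": (1.0, 100.0),
        }
        try:
            q, r = presets[which]
        except KeyError:
            raise ValueError(f"unknown preset {which!r}; choose from {sorted(presets)}")
        return cls(Q=q * np.eye(5), R=r * np.eye(2))


@dataclass(frozen=True)
class WalkerParams:
    """Full parameter set for one simulation: mechanics + muscles + control."""

    model: ModelParams = field(default_factory=ModelParams)
    rf: MuscleParams = field(default_factory=default_rf)
    ham: MuscleParams = field(default_factory=default_ham)
    reflex: ReflexParams = field(default_factory=ReflexParams)
    fmch: FMCHParams = field(default_factory=FMCHParams)

    def replace(self, **kwargs) -> "WalkerParams":
        return replace(self, **kwargs)


def _section(obj) -> dict:
    d = asdict(obj)
    return {k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v)
            for k, v in d.items()}


def save_config(params: WalkerParams, path: str | Path) -> None:
    """Write the full parameter set to a YAML file, one section per table."""
    doc = {
        "model": _section(params.model),
        "muscle_rf": _section(params.rf),
        "muscle_ham": _section(params.ham),
        "reflex": _section(params.reflex),
        "fmch": _section(params.fmch),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> WalkerParams:
    """Read a parameter YAML written by :func:`save_config`.

    Missing sections or keys fall back to the defaults, so a config file may
    override only what it needs to.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    base = WalkerParams()

    def build(cls, section, default):
        if section not in doc:
            return default
        return replace(default, **doc[section])

    return WalkerParams(
        model=build(ModelParams, "model", base.model),
        rf=build(MuscleParams, "muscle_rf", base.rf),
        ham=build(MuscleParams, "muscle_ham", base.ham),
        reflex=build(ReflexParams, "reflex", base.reflex),
        fmch=build(FMCHParams, "fmch", base.fmch),
    )
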