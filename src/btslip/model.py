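"""Model/Results interface to the walker, in the style of statistical
modelling packages: build a :class:`GaitModel` for one controller, call
``fit()`` to locate (and characterize) its limit cycle, and use the
returned :class:`GaitResults` for simulation, perturbation studies, basin
sweeps, virtual-pivot-point estimation and plotting.

>>> res = GaitModel("nmf").fit()
>>> print(res.summary())
>>> run = res.simulate(n_steps=50)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import (BasinGrid, FixedPoint, VPPEstimate,
                       basin_of_attraction, estimate_vpp,
                       find_limit_cycle, qr_tradeoff)
from .controllers import (AdaptiveNMFController, FMCHController,
                          NMFController, PreflexController, PreflexLibrary,
                          StepToStepMap, linearize, solve_dlqr,
                          NMF_GAINS_CALIBRATED)
from .engine import (PerturbationSpec, SimResult, Simulator, recovery_time)
from .params import LQRConfig, WalkerParams, load_config

__all__ = ["GaitModel", "GaitResults"]

_CONTROLLERS = ("fmch", "nmf", "preflex", "adaptive_nmf")


class GaitModel:
    """A walker + balance-controller pair, ready to be fitted.

    Parameters
    ----------
    controller : one of 'fmch', 'nmf', 'preflex', 'adaptive_nmf'
    params : WalkerParams, optional
        Mechanical/muscle/reflex parameter bundles (published defaults).
    speed_target : float
        Forward speed of the gait the fit targets, m/s.
    gains : (G_RF, G_HAM), optional
        Reflex gains for nmF-family controllers; defaults to the package's
        calibrated stable-gait pair.
    lqr : LQRConfig, optional
        Weighting and iteration controls for the adaptive controller.
    """

    def __init__(self, controller: str = "nmf",
                 params: Optional[WalkerParams] = None,
                 speed_target: float = 1.0,
                 gains=None, lqr: Optional[LQRConfig] = None,
                 h: float = 2.5e-4):
        controller = controller.lower()
        if controller not in _CONTROLLERS:
            raise ValueError(f"controller must be one of {_CONTROLLERS}")
        self.controller = controller
        self.params = params or WalkerParams()
        self.speed_target = speed_target
        self.gains = tuple(gains) if gains is not None else NMF_GAINS_CALIBRATED
        self.lqr = lqr or LQRConfig()
        self.h = h

    @classmethod
    def from_config(cls, path, controller: str = "nmf", **kw) -> "GaitModel":
        """Build a model from a YAML parameter file."""
        return cls(controller=controller, params=load_config(path), **kw)

    # -- fitting --------------------------------------------------------------

    def fit(self, guess=None) -> "GaitResults":
        """Locate the controller's 1 m/s period-1 limit cycle and
        characterize it (step-map Jacobian, eigenvalues, stride metrics;
        LQR design for the adaptive controller; activation library for the
        preflex controller)."""
        base_kind = "nmf" if self.controller in ("preflex", "adaptive_nmf") \
            else self.controller
        speed = self.speed_target if base_kind == "fmch" else None
        fp = find_limit_cycle(self.params, base_kind, guess=guess,
                              speed_target=speed, h=self.h)

        U_star = np.array([self.gains[1], self.gains[0]])  # (G_HAM, G_RF)
        ctx = StepToStepMap(self.params, kind=base_kind, h=self.h)
        if base_kind == "nmf":
            A_s, B_s = linearize(ctx, fp.S_star, U_star)
        else:
            A_s, _ = linearize(lambda S, U=None: ctx(S), fp.S_star,
                               np.zeros(2))
            B_s = None

        library = None
        K = P = None
        if self.controller == "preflex":
            library = PreflexLibrary.from_result(fp.cycle)
        elif self.controller == "adaptive_nmf":
            K, P = solve_dlqr(A_s, B_s, self.lqr.Q, self.lqr.R,
                              tol=self.lqr.tol, max_iter=self.lqr.max_iter)

        return GaitResults(model=self, fixed_point=fp, A_s=A_s, B_s=B_s,
                           K=K, P=P, library=library)


@dataclass
class GaitResults:
    """Fitted gait: the limit cycle, its linearization, and study methods."""

    model: GaitModel
    fixed_point: FixedPoint
    A_s: np.ndarray
    B_s: Optional[np.ndarray] = None
    K: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None
    library: Optional[PreflexLibrary] = None

    # -- basic quantities -----------------------------------------------------

    @property
    def S_star(self) -> np.ndarray:
        return self.fixed_point.S_star

    @property
    def U_star(self) -> np.ndarray:
        g_rf, g_ham = self.model.gains
        return np.array([g_ham, g_rf])

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A_s)

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(self.eigenvalues)))

    @property
    def cycle(self) -> SimResult:
        return self.fixed_point.cycle

    def stride_metrics(self) -> pd.Series:
        """Converged-stride summary: duration, speed, hip energy, duty
        factor, and peak-to-peak vertical CoM excursion (cm)."""
        strides = self.cycle.strides
        st = strides.iloc[len(strides) // 2]
        traj = self.cycle.trajectory
        w = traj[(traj["t"] >= st["t_start"]) & (traj["t"] <= st["t_end"])]
        exc = float(w["y"].max() - w["y"].min()) * 100.0
        return pd.Series({
            "stride_duration": st["duration"],
            "stride_speed": st["speed"],
            "stride_energy": st["energy"],
            "duty_factor": st["duty_factor"],
            "com_excursion_cm": exc,
        })

    # -- studies --------------------------------------------------------------

    def make_controller(self):
        m = self.model
        if m.controller == "fmch":
            return FMCHController(m.params.fmch)
        if m.controller == "nmf":
            return NMFController(np.asarray(m.gains))
        if m.controller == "preflex":
            return PreflexController(self.library)
        return AdaptiveNMFController(self.K, self.S_star, self.U_star,
                                     gain_floor=m.lqr.gain_floor)

    def simulate(self, n_steps: int = 50,
                 perturbation: Optional[PerturbationSpec] = None,
                 record: bool = True, S0=None) -> SimResult:
        """Walk from the fitted cycle (or ``S0``), optionally perturbed."""
        sim = Simulator(self.model.params, self.make_controller(),
                        h=self.model.h, record=record, rec_every=2)
        offsets = (0.0, 0.0)
        if self.model.controller == "preflex":
            offsets = self.library.td_offsets_at_midstance()
        sim.init_midstance(self.S_star if S0 is None else S0,
                           td_offsets=offsets)
        return sim.run(n_steps=n_steps, speed_target=self.model.speed_target,
                       perturbation=perturbation)

    def recovery(self, perturbation: Optional[PerturbationSpec] = None,
                 n_steps: int = 50, band: float = math.radians(2.0)):
        """Perturbed run plus the trunk-pattern recovery time."""
        res = self.simulate(n_steps=n_steps,
                            perturbation=perturbation or PerturbationSpec())
        return recovery_time(res, band=band), res

    def basin(self, phi_values=None, phidot_values=None, n_steps: int = 50,
              progress=None) -> BasinGrid:
        """Basin-of-attraction sweep over mid-stance (phi, phidot)."""
        return basin_of_attraction(
            self.model.params, self.make_controller, self.S_star,
            phi_values=phi_values, phidot_values=phidot_values,
            n_steps=n_steps, speed_target=self.model.speed_target,
            model=self.model.controller, h=self.model.h, progress=progress)

    def vpp(self, min_fy: float = 20.0) -> VPPEstimate:
        """Virtual pivot point of the converged cycle."""
        strides = self.cycle.strides
        st = strides.iloc[len(strides) // 2]
        traj = self.cycle.trajectory
        w = traj[(traj["t"] >= st["t_start"]) & (traj["t"] <= st["t_end"])]
        return estimate_vpp(w, min_fy=min_fy)

    def qr_study(self, presets=("performance", "balanced", "efficiency"),
                 **kw) -> pd.DataFrame:
        if self.B_s is None:
            raise ValueError("Q/R study requires an nmF-family fit")
        return qr_tradeoff(self.model.params, self.S_star, self.U_star,
                           self.A_s, self.B_s, presets=presets, **kw)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        fp = self.fixed_point
        sm = self.stride_metrics()
        lams = np.sort(np.abs(self.eigenvalues))[::-1]
        lines = [
            "        BTSLIP gait fit",
            "=" * 46,
            f"controller:        {self.model.controller}",
            f"speed target:      {self.model.speed_target:.3f} m/s",
            f"fixed point S*:    vx={fp.S_star[0]:+.4f} m/s  y={fp.S_star[1]:.4f} m",
            f"                   vy={fp.S_star[2]:+.4f} m/s  phi={math.degrees(fp.S_star[3]):.2f} deg",
            f"                   phidot={fp.S_star[4]:+.4f} rad/s",
            f"map residual:      {fp.residual:.2e}",
            f"step time/length:  {fp.step_time:.3f} s / {fp.step_length:.3f} m",
            f"stride duration:   {sm.stride_duration:.3f} s",
            f"stride energy:     {sm.stride_energy:.2f} J",
            f"duty factor:       {sm.duty_factor:.3f}",
            f"CoM excursion:     {sm.com_excursion_cm:.2f} cm",
            f"|eigenvalues|:     {np.array2string(lams, precision=4)}",
            f"spectral radius:   {self.spectral_radius:.4f}",
        ]
        if self.K is not None:
            lines.append(f"LQR gain K:        {np.array2string(self.K, precision=3)}")
        return "\n".join(lines)
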