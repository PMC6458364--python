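"""Gait analysis: limit-cycle search, calibration, basin-of-attraction
sweeps, virtual-pivot-point estimation, LQR weighting studies, and the
synthetic human-like reference curves used by the comparison/plot API.

Shipped default fixed-point guesses (``DEFAULT_GUESSES``) are coarse
mid-stance states near the 1 m/s gaits of each controller; the limit-cycle
search polishes them to machine precision at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .controllers import (AdaptiveNMFController, FallError,
                          PreflexLibrary, StepToStepMap, linearize,
                          solve_dlqr)
from .engine import (PerturbationSpec, SimResult, Simulator, peak_hip_power,
                     recovery_time)
from .params import FMCHParams, LQRConfig, ReflexParams, WalkerParams

__all__ = [
    "FixedPoint",
    "BasinGrid",
    "VPPEstimate",
    "ReferenceCurves",
    "DEFAULT_GUESSES",
    "find_limit_cycle",
    "calibrate_fmch",
    "calibrate_nmf_gains",
    "basin_of_attraction",
    "estimate_vpp",
    "qr_tradeoff",
    "generate_reference_curves",
]

#: Coarse mid-stance guesses (vx, y, vy, phi, phidot) near the 1 m/s gaits.
DEFAULT_GUESSES = {
    "fmch": np.array([0.998, 1.0910, 0.0, math.pi / 2, 0.0446]),
    "nmf": np.array([0.9982, 1.0908, 0.0005, 1.5721, 0.0567]),
}


@dataclass
class FixedPoint:
    """A converged period-1 mid-stance fixed point and its gait cycle."""

    S_star: np.ndarray
    residual: float
    speed: float
    step_time: float
    controller: str
    cycle: Optional[SimResult] = None

    @property
    def step_length(self) -> float:
        return self.speed * self.step_time


def find_limit_cycle(params: WalkerParams, controller: str = "nmf",
                     guess=None, speed_target: Optional[float] = None,
                     tol: float = 1e-8, library: Optional[PreflexLibrary] = None,
                     record_cycle: bool = True, h: float = 2.5e-4,
                     n_record_strides: int = 8) -> FixedPoint:
    """Locate the period-1 mid-stance fixed point of a controller.

    Runs a damped least-squares (Levenberg-Marquardt) iteration on the
    residual ``P(S) - S`` of the step-to-step map; if ``speed_target`` is
    given, the mean step speed is appended as a sixth residual (required
    for the FMCH, whose symmetric gaits form a speed-neutral family).
    Raises ``RuntimeError`` with the last residual on non-convergence.
    """
    ctx = StepToStepMap(params, kind=controller, library=library, h=h)
    if guess is None:
        guess = DEFAULT_GUESSES.get(controller)
        if guess is None:
            raise ValueError(f"no shipped guess for controller {controller!r}; "
                             "pass one explicitly")
    guess = np.asarray(guess, dtype=float)

    def residual(S):
        try:
            Sn = ctx(S)
        except (FallError, ArithmeticError):
            n = 6 if speed_target is not None else 5
            return np.full(n, 10.0)
        r = Sn - S
        if speed_target is not None:
            r = np.append(r, ctx.step_speed() - speed_target)
        return r

    sol = least_squares(residual, guess, diff_step=1e-6,
                        xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=400)
    res = float(np.linalg.norm(sol.fun))
    if res > tol:
        raise RuntimeError(
            f"limit-cycle search for {controller!r} did not converge: "
            f"residual {res:.3e} > {tol:g}")
    S_star = sol.x
    ctx(S_star)
    fp = FixedPoint(S_star=S_star, residual=res, speed=ctx.step_speed(),
                    step_time=ctx.last_step_time, controller=controller)
    if record_cycle:
        fp.cycle = _record_cycle(params, controller, S_star, library,
                                 n_record_strides, h)
    return fp


def _record_cycle(params, controller, S_star, library, n_strides, h):
    from .controllers import make_controller
    ctrl = make_controller(controller, params, library=library)
    sim = Simulator(params, ctrl, h=h, record=True, rec_every=2)
    offsets = (0.0, 0.0)
    if controller == "preflex":
        offsets = library.td_offsets_at_midstance()
    sim.init_midstance(S_star, td_offsets=offsets)
    return sim.run(n_steps=2 * n_strides + 2, speed_target=1.0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_fmch(params: Optional[WalkerParams] = None,
                   speed_target: float = 1.0,
                   G_candidates=(0.4, 0.5, 0.6)) -> tuple[FMCHParams, np.ndarray]:
    """Deterministic FMCH calibration for a 1 m/s period-1 gait.

    The spring rest angle is fixed at the steady mid-stance hip angle
    (``phi_h0 = pi``, an upright trunk over a vertical leg); candidate
    normalized stiffnesses are screened by the spectral radius of the step
    map restricted to the non-neutral directions (the symmetric gait family
    is speed-neutral) and the most contracting candidate is returned with
    its fixed point.
    """
    base = params or WalkerParams()
    best = None
    for G in G_candidates:
        p = base.replace(fmch=FMCHParams(G=G, phi_h0=math.pi))
        try:
            fp = find_limit_cycle(p, "fmch", speed_target=speed_target,
                                  record_cycle=False)
            ctx = StepToStepMap(p, kind="fmch")
            A, _ = linearize(lambda S, U=None: ctx(S), fp.S_star,
                             np.zeros(2))
            lams = np.sort(np.abs(np.linalg.eigvals(A)))[::-1]
            rho_rest = lams[1]  # drop the neutral speed direction
        except (RuntimeError, FallError, ArithmeticError):
            continue
        if best is None or rho_rest < best[0]:
            best = (rho_rest, G, fp.S_star)
    if best is None:
        raise RuntimeError("FMCH calibration failed for all candidates")
    _, G, S_star = best
    return FMCHParams(G=G, phi_h0=math.pi), S_star


def calibrate_nmf_gains(params: Optional[WalkerParams] = None,
                        speed_target: float = 1.0,
                        scales=(1.5, 2.0, 2.5),
                        ratio_guess: float = 1.6) -> tuple[tuple[float, float], np.ndarray]:
    """Deterministic reflex-gain calibration for a 1 m/s period-1 nmF gait.

    For each overall gain scale ``s`` (G_RF = s / F_max) the HAM:RF ratio
    and the mid-stance state are solved jointly so that the step map closes
    at the target speed (the ratio is pinned by the trunk-torque and
    hip-work balances, which a steady upright gait must satisfy
    simultaneously); the scale with the smallest spectral radius wins.
    Returns ``((G_RF, G_HAM), S_star)``.
    """
    base = params or WalkerParams()
    F_max = base.rf.F_max
    z0 = np.append(DEFAULT_GUESSES["nmf"], ratio_guess)
    best = None
    for s in scales:
        def residual(z):
            S, ratio = z[:5], abs(z[5])
            rx = ReflexParams(G_RF=s / F_max, G_HAM=ratio * s / F_max)
            ctx = StepToStepMap(base.replace(reflex=rx), kind="nmf")
            try:
                Sn = ctx(S, np.array([ratio * s / F_max, s / F_max]))
            except (FallError, ArithmeticError):
                return np.full(6, 10.0)
            return np.append(Sn - S, ctx.step_speed() - speed_target)

        sol = least_squares(residual, z0, diff_step=1e-6, xtol=3e-16,
                            ftol=3e-16, gtol=3e-16, max_nfev=400)
        if np.linalg.norm(sol.fun) > 1e-9:
            continue
        z0 = sol.x.copy()
        S, ratio = sol.x[:5], abs(sol.x[5])
        gains = (s / F_max, ratio * s / F_max)
        p = base.replace(reflex=ReflexParams(G_RF=gains[0], G_HAM=gains[1]))
        ctx = StepToStepMap(p, kind="nmf")
        try:
            A, _ = linearize(lambda Sv, U=None: ctx(Sv, np.array([gains[1], gains[0]])),
                             S, np.array([gains[1], gains[0]]))
            rho = np.max(np.abs(np.linalg.eigvals(A)))
        except (FallError, ArithmeticError):
            continue
        if best is None or rho < best[0]:
            best = (rho, gains, S)
    if best is None:
        raise RuntimeError("nmF gain calibration failed for all scales")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# basin of attraction
# ---------------------------------------------------------------------------

@dataclass
class BasinGrid:
    """Boolean stability map over mid-stance (phi, phidot) initial
    conditions, with the untouched Poincare coordinates held at the
    limit-cycle values."""

    phi_values: np.ndarray      # rad
    phidot_values: np.ndarray   # rad/s
    stable: np.ndarray          # bool, shape (len(phi), len(phidot))
    model: str = ""

    def __post_init__(self):
        if self.stable.shape != (len(self.phi_values), len(self.phidot_values)):
            raise ValueError("stability matrix does not match the grids")

    @property
    def cell_area(self) -> float:
        dphi = float(np.mean(np.diff(self.phi_values))) if len(self.phi_values) > 1 else 1.0
        dpd = float(np.mean(np.diff(self.phidot_values))) if len(self.phidot_values) > 1 else 1.0
        return dphi * dpd

    @property
    def area(self) -> float:
        """Stable count times cell area, rad^2/s."""
        return float(self.stable.sum()) * self.cell_area

    def to_frame(self) -> pd.DataFrame:
        phi, pd_ = np.meshgrid(self.phi_values, self.phidot_values,
                               indexing="ij")
        return pd.DataFrame({"phi": phi.ravel(), "phidot": pd_.ravel(),
                             "stable": self.stable.ravel().astype(int)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


#: default grid of the published sweep: trunk angle 60-120 deg step 1 deg,
#: angular velocity -200..150 deg/s step 0.1 rad/s
def default_basin_grid():
    phi = np.radians(np.arange(60.0, 120.0 + 1e-9, 1.0))
    phidot = np.arange(math.radians(-200.0), math.radians(150.0) + 1e-9, 0.1)
    return phi, phidot


def coarse_basin_grid():
    """Desk-scale preset: 5 deg x 0.2 rad/s (~500 cells)."""
    phi = np.radians(np.arange(60.0, 120.0 + 1e-9, 5.0))
    phidot = np.arange(math.radians(-200.0), math.radians(150.0) + 1e-9, 0.2)
    return phi, phidot


def basin_of_attraction(params: WalkerParams, controller_factory: Callable,
                        S_star, phi_values=None, phidot_values=None,
                        n_steps: int = 50, speed_target: float = 1.0,
                        settle_steps: int = 5, speed_tol: float = 0.05,
                        model: str = "", h: float = 2.5e-4,
                        progress: Optional[Callable] = None) -> BasinGrid:
    """Sweep mid-stance (phi, phidot) initial conditions and record which
    cells walk ``n_steps`` without falling and return to the target speed.

    ``controller_factory`` is called once per cell (adaptation state must
    not leak between cells).  A cell is stable when all steps complete and
    the mean speeds of the last ``settle_steps`` steps are within
    ``speed_tol`` of the target.  Any per-cell failure (fall, numerical)
    marks the cell unstable; the sweep never aborts.
    """
    if phi_values is None or phidot_values is None:
        phi_values, phidot_values = coarse_basin_grid()
    phi_values = np.asarray(phi_values, float)
    phidot_values = np.asarray(phidot_values, float)
    S_star = np.asarray(S_star, float)
    stable = np.zeros((len(phi_values), len(phidot_values)), dtype=bool)
    for i, phi in enumerate(phi_values):
        for j, pdot in enumerate(phidot_values):
            S = S_star.copy()
            S[3] = phi
            S[4] = pdot
            ok = False
            try:
                sim = Simulator(params, controller_factory(), h=h,
                                record=False)
                sim.init_midstance(S)
                res = sim.run(n_steps=n_steps, speed_target=speed_target,
                              speed_tol=10.0)
                if res.n_steps_completed >= n_steps and len(res.steps) >= settle_steps:
                    tail = res.steps["speed"].iloc[-settle_steps:]
                    ok = bool((np.abs(tail - speed_target)
                               <= speed_tol * speed_target).all())
            except (ValueError, FallError, ArithmeticError):
                ok = False
            stable[i, j] = ok
        if progress is not None:
            progress(i + 1, len(phi_values))
    return BasinGrid(phi_values=phi_values, phidot_values=phidot_values,
                     stable=stable, model=model)


# ---------------------------------------------------------------------------
# virtual pivot point
# ---------------------------------------------------------------------------

@dataclass
class VPPEstimate:
    """Least-squares intersection of stance GRF lines in the trunk-fixed,
    CoM-centred frame (ordinate along the trunk axis)."""

    point: tuple[float, float]
    residual: float          # RMS perpendicular distance, m
    n_lines: int

    @property
    def height(self) -> float:
        """Height of the VPP above the CoM along the trunk axis, m."""
        return self.point[1]


def estimate_vpp(traj: pd.DataFrame, min_fy: float = 20.0,
                 cond_limit: float = 1e8) -> VPPEstimate:
    """Estimate the virtual pivot point from a recorded gait cycle.

    Every loaded stance sample contributes the line through its foot point
    along its GRF vector, transformed into the trunk frame (origin at the
    CoM, ordinate along the trunk axis); the VPP is the point minimizing
    the summed squared perpendicular distances to all lines.
    """
    pts = []
    dirs = []
    for leg in range(2):
        sub = traj[(traj[f"contact_{leg}"] > 0)
                   & (traj[f"grf_y_{leg}"] > min_fy)]
        if not len(sub):
            continue
        gx = sub[f"grf_x_{leg}"].to_numpy()
        gy = sub[f"grf_y_{leg}"].to_numpy()
        fx = sub[f"foot_x_{leg}"].to_numpy()
        phi = sub["phi"].to_numpy()
        cx = sub["x"].to_numpy()
        cy = sub["y"].to_numpy()
        # rotate by (pi/2 - phi): trunk axis becomes the +y ordinate
        th = math.pi / 2 - phi
        c, s = np.cos(th), np.sin(th)
        px = fx - cx
        py = -cy
        pts.append(np.column_stack([c * px - s * py, s * px + c * py]))
        dirs.append(np.column_stack([c * gx - s * gy, s * gx + c * gy]))
    if not pts:
        raise ValueError("no loaded stance samples in the trajectory")
    p = np.vstack(pts)
    d = np.vstack(dirs)
    n = len(p)
    if n < 10:
        raise ValueError("need at least 10 loaded stance samples")
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    # normal equations: sum(I - d d^T) v = sum(I - d d^T) p
    M = np.zeros((2, 2))
    b = np.zeros(2)
    for k in range(n):
        Pk = np.eye(2) - np.outer(d[k], d[k])
        M += Pk
        b += Pk @ p[k]
    if np.linalg.cond(M) > cond_limit:
        raise ValueError("GRF lines are near-parallel; VPP ill-conditioned")
    v = np.linalg.solve(M, b)
    r = v - p
    perp = r - d * np.sum(r * d, axis=1, keepdims=True)
    rms = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return VPPEstimate(point=(float(v[0]), float(v[1])), residual=rms,
                       n_lines=n)


# ---------------------------------------------------------------------------
# LQR weighting study
# ---------------------------------------------------------------------------

def qr_tradeoff(params: WalkerParams, S_star, U_star, A_s, B_s,
                presets=("performance", "balanced", "efficiency"),
                perturbation: Optional[PerturbationSpec] = None,
                n_steps: int = 30, h: float = 2.5e-4) -> pd.DataFrame:
    """Run the standard trunk push under each LQR weighting preset and
    report recovery time, per-stride hip energy, and peak hip power."""
    if perturbation is None:
        perturbation = PerturbationSpec()
    rows = []
    for name in presets:
        cfg = LQRConfig.preset(name)
        K, _ = solve_dlqr(A_s, B_s, cfg.Q, cfg.R, tol=cfg.tol,
                          max_iter=cfg.max_iter)
        ctrl = AdaptiveNMFController(K, S_star, U_star,
                                     gain_floor=cfg.gain_floor)
        sim = Simulator(params, ctrl, h=h, record=True, rec_every=4)
        sim.init_midstance(S_star)
        res = sim.run(n_steps=n_steps, speed_target=1.0,
                      perturbation=perturbation)
        rec = recovery_time(res)
        post = res.strides[res.strides["t_start"]
                           >= (res.perturbation_time or 0.0) - 1e-9]
        tp = res.perturbation_time
        window = res.trajectory[res.trajectory["t"] >= (tp or 0.0)]
        rows.append({
            "preset": name,
            "recovery_time": rec,
            "steps_completed": res.n_steps_completed,
            "mean_stride_energy": float(post["energy"].mean()) if len(post) else math.nan,
            "max_stride_energy": float(post["energy"].max()) if len(post) else math.nan,
            "peak_hip_power": peak_hip_power(window),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic reference curves (fixture for the comparison/plot API)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceCurves:
    """Synthetic mean +- band gait curves over one stride (fixture).

    These emulate the qualitative structure of treadmill-walking group
    curves (double-humped vertical GRF near 1.1 BW, ~5 cm CoM vertical
    excursion, smooth hip-torque wave) purely to exercise the comparison
    and plotting API; they are not human data.
    """

    phase: np.ndarray            # stride fraction in [0, 1)
    grf_vertical: np.ndarray     # mean, BW
    grf_vertical_band: np.ndarray
    grf_horizontal: np.ndarray   # mean, BW
    grf_horizontal_band: np.ndarray
    com_displacement: np.ndarray  # mean, cm (about 0)
    com_displacement_band: np.ndarray
    hip_torque: np.ndarray       # mean, torque normalized to BW (m)
    hip_torque_band: np.ndarray


def generate_reference_curves(seed: int = 0, n: int = 200,
                              duty: float = 0.65) -> ReferenceCurves:
    """Deterministic synthetic stride curves (same seed, same curves).

    One leg's stance occupies the first ``duty`` fraction of the stride;
    its vertical GRF is a double-humped (M-shaped) profile peaking near
    1.1 BW, the horizontal GRF is a braking/propulsion S-wave, the CoM
    vertical displacement is double-humped with ~5 cm peak-to-peak, and
    the hip torque is a smooth extension-to-flexion wave.  Bands are
    seeded smooth positive envelopes (~10% of signal scale).
    """
    rng = np.random.default_rng(seed)
    s = np.arange(n) / n

    tau = np.clip(s / duty, 0.0, 1.0)  # stance-local phase of the leg
    in_st = s < duty

    def bump(x, mu, sig):
        return np.exp(-0.5 * ((x - mu) / sig) ** 2)

    vg = 1.16 * bump(tau, 0.22, 0.13) + 1.16 * bump(tau, 0.78, 0.13)
    vg *= in_st
    hg = 0.18 * np.sin(2.0 * math.pi * tau) * bump(tau, 0.5, 0.35) * -1.0
    hg *= in_st
    com = 2.5 * np.cos(4.0 * math.pi * (s - 0.03))          # cm, p2p ~5
    hip = 0.06 * np.sin(2.0 * math.pi * s) + 0.025 * np.sin(4.0 * math.pi * s)

    def band(scale):
        raw = rng.normal(0.0, 1.0, 8)
        ph = 2.0 * math.pi * s
        env = np.ones(n)
        for k2, a in enumerate(raw):
            env += 0.1 * a * np.cos((k2 + 1) * ph + k2)
        return scale * np.clip(env, 0.3, 2.0)

    return ReferenceCurves(
        phase=s,
        grf_vertical=vg, grf_vertical_band=band(0.08),
        grf_horizontal=hg, grf_horizontal_band=band(0.03),
        com_displacement=com - com.mean(), com_displacement_band=band(0.5),
        hip_torque=hip, hip_torque_band=band(0.012),
    )
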