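"""Figures: gait curves vs reference bands, basin maps, VPP geometry."""

from __future__ import annotations

import math

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_gait_curves", "plot_basin", "plot_vpp"]


def _stride_window(result):
    st = result.strides.iloc[len(result.strides) // 2]
    traj = result.trajectory
    w = traj[(traj["t"] >= st["t_start"]) & (traj["t"] <= st["t_end"])]
    phase = (w["t"] - st["t_start"]) / st["duration"]
    return w, phase.to_numpy()


def plot_gait_curves(result, params, reference=None, label="model"):
    """Four-panel stride plot (CoM displacement, hip torque/BW, horizontal
    and vertical GRF/BW) with optional synthetic reference bands."""
    w, s = _stride_window(result)
    bw = params.model.m * params.model.g
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), constrained_layout=True)
    panels = [
        ("CoM vertical displacement (cm)",
         (w["y"] - w["y"].iloc[0]) * 100.0, "com_displacement"),
        ("hip torque / BW (m)",
         (w["tau_0"].fillna(0) + w["tau_1"].fillna(0)) / bw, "hip_torque"),
        ("horizontal GRF / BW",
         (w["grf_x_0"] + w["grf_x_1"]) / bw, "grf_horizontal"),
        ("vertical GRF / BW",
         (w["grf_y_0"] + w["grf_y_1"]) / bw, "grf_vertical"),
    ]
    for ax, (title, series, refname) in zip(axes.ravel(), panels):
        if reference is not None:
            mean = getattr(reference, refname)
            band = getattr(reference, refname + "_band")
            ax.fill_between(reference.phase, mean - band, mean + band,
                            alpha=0.3, color="c", label="reference band")
            ax.plot(reference.phase, mean, "c-", lw=1)
        ax.plot(s, series, "b--", lw=1.5, label=label)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("stride fraction")
    axes[0, 0].legend(fontsize=7)
    return fig


def plot_basin(grid, ax=None):
    """Stability map over mid-stance trunk angle and angular velocity."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(np.degrees(grid.phidot_values), np.degrees(grid.phi_values),
                  grid.stable.astype(float), shading="auto", cmap="Greens")
    ax.set_xlabel("trunk angular velocity (deg/s)")
    ax.set_ylabel("trunk angle (deg)")
    ax.set_title(f"basin of attraction: {grid.model} "
                 f"(area {grid.area:.3f} rad^2/s)", fontsize=9)
    return ax.figure


def plot_vpp(result, params, vpp, n_lines=40, ax=None):
    """Stance GRF lines in the trunk-fixed CoM-centred frame with the
    estimated virtual pivot point."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 5))
    w, _ = _stride_window(result)
    idx = np.linspace(0, len(w) - 1, n_lines).astype(int)
    for leg in range(2):
        sub = w.iloc[idx]
        sub = sub[(sub[f"contact_{leg}"] > 0) & (sub[f"grf_y_{leg}"] > 20.0)]
        for _, r in sub.iterrows():
            th = math.pi / 2 - r["phi"]
            c, s = math.cos(th), math.sin(th)
            px, py = r[f"foot_x_{leg}"] - r["x"], -r["y"]
            dx, dy = r[f"grf_x_{leg}"], r[f"grf_y_{leg}"]
            p = np.array([c * px - s * py, s * px + c * py])
            d = np.array([c * dx - s * dy, s * dx + c * dy])
            d = d / np.linalg.norm(d)
            span = np.array([-0.2, 1.6])
            ax.plot(p[0] + span * d[0], p[1] + span * d[1], color="0.7",
                    lw=0.5)
    ax.plot(0, 0, "go", label="CoM")
    ax.plot(*vpp.point, "ro", label="VPP")
    ax.set_xlim(-0.6, 0.6)
    ax.set_ylim(-1.2, 0.6)
    ax.set_xlabel("x (trunk frame, m)")
    ax.set_ylabel("y (trunk frame, m)")
    ax.legend(fontsize=8)
    return ax.figure
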