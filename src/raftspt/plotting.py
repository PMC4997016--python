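"""Convenience plots for MSD curves, exponent histograms, trajectories and
confinement levels. The CSV reports are the contract; these helpers exist for
quick visual inspection."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .msd import MSDCurve
from .trajectory import Trajectory


def plot_msd(curves, ensemble: MSDCurve | None = None, ax=None, **kwargs):
    """Log-log MSD plot of individual curves (grey) and an ensemble (thick)."""
    if ax is None:
        _, ax = plt.subplots()
    for c in np.atleast_1d(curves):
        ax.loglog(c.lag_s, c.msd_um2, color="0.7", lw=0.5, **kwargs)
    if ensemble is not None:
        ax.loglog(ensemble.lag_s, ensemble.msd_um2, color="k", lw=2)
    ax.set_xlabel(r"lag $\Delta t$ (s)")
    ax.set_ylabel(r"MSD ($\mu m^2$)")
    return ax


def plot_alpha_hist(alphas, ax=None, bins=25):
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(alphas), bins=bins, color="steelblue", edgecolor="k")
    ax.axvline(1.0, color="r", ls="--", lw=1)
    ax.set_xlabel(r"anomalous exponent $\alpha$")
    ax.set_ylabel("count")
    return ax


def plot_trajectory(traj: Trajectory, ax=None, color_by_state: bool = True):
    if ax is None:
        _, ax = plt.subplots()
    if color_by_state and traj.state is not None:
        colors = np.array(["tab:red", "tab:blue", "tab:purple"])
        st = np.asarray(traj.state, dtype=int)
        ax.scatter(traj.x, traj.y, c=colors[st], s=1)
    else:
        ax.plot(traj.x, traj.y, lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel(r"x ($\mu m$)")
    ax.set_ylabel(r"y ($\mu m$)")
    return ax


def plot_probability_level(t_s, L_raw, L_smooth, l_critical=1.0, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(t_s, L_raw, color="0.7", lw=0.5, label="raw L")
    ax.plot(t_s, L_smooth, color="k", lw=1.2, label="smoothed")
    ax.axhline(l_critical, color="r", ls="--", lw=1, label=r"$L_c$")
    ax.set_xlabel("t (s)")
    ax.set_ylabel("probability level L")
    ax.legend(frameon=False)
    return ax
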