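"""Figure helpers mirroring the standard presentation of the simulations:
displacement/velocity traces under a precision sweep, simulated dopaminergic
firing, and delay-period belief rasters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_trial(result, ax=None):
    """Displacement and speed of one trial, with epoch boundaries dashed."""
    if ax is None:
        _, ax = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    traj = result.trajectory
    disp = np.linalg.norm(traj.positions - traj.positions[0], axis=1)
    ax[0].plot(traj.times, disp, color="k")
    ax[0].set_ylabel("displacement (deg)")
    ax[1].plot(traj.times, traj.speed, color="k")
    ax[1].set_ylabel("speed (deg/s)")
    ax[1].set_xlabel("time (s)")
    for b in traj.segment_bounds[1:]:
        for a in ax:
            a.axvline(traj.times[b], ls="--", color="grey", lw=0.8)
    return ax


def plot_sweep_trajectories(results_by_value, title, ax=None):
    """Overlay displacement/velocity traces for each parameter value."""
    if ax is None:
        _, ax = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    cmap = plt.get_cmap("viridis")
    values = sorted(results_by_value)
    for i, v in enumerate(values):
        r = results_by_value[v]
        traj = r.trajectory
        disp = np.linalg.norm(traj.positions - traj.positions[0], axis=1)
        c = cmap(i / max(len(values) - 1, 1))
        ax[0].plot(traj.times, disp, color=c, label=f"{v:g}")
        ax[1].plot(traj.times, traj.speed, color=c)
    ax[0].set_ylabel("displacement (deg)")
    ax[0].set_title(title)
    ax[0].legend(title="value", fontsize=8)
    ax[1].set_ylabel("speed (deg/s)")
    ax[1].set_xlabel("time (s)")
    return ax


def plot_dose_response(table, y="peak_velocity", ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["value"], table[y], "o-k")
    ax.set_xscale("log")
    ax.set_xlabel(table.parameter)
    ax.set_ylabel(y.replace("_", " "))
    return ax


def plot_gamma_traces(beta_grid, traces, ax=None):
    """Simulated dopaminergic firing: expected precision per update iteration,
    one panel per prior precision level (highest gamma on top)."""
    n = len(beta_grid)
    if ax is None:
        _, ax = plt.subplots(n, 1, figsize=(6, 1.8 * n), sharex=True)
    order = np.argsort(beta_grid)  # ascending beta = descending gamma
    for row, i in enumerate(order):
        ax[row].plot(traces[i], color="k")
        ax[row].axhline(1.0 / beta_grid[i], ls=":", color="grey", lw=0.8)
        ax[row].set_ylabel(f"$\\gamma$ ({1.0 / beta_grid[i]:g})")
    ax[-1].set_xlabel("update iteration")
    return ax


def plot_raster(raster, ax=None):
    """Delay-period firing raster: rows are target-location populations at
    each represented time, columns are observation epochs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(1.0 - raster.matrix, cmap="gray", aspect="auto",
              vmin=0.0, vmax=1.0, interpolation="nearest")
    n_targ = raster.matrix.shape[0] // raster.matrix.shape[1]
    for k in range(1, raster.matrix.shape[1]):
        ax.axhline(k * n_targ - 0.5, color="red", lw=0.5)
    ax.set_xlabel("epoch")
    ax.set_ylabel("target population x represented time")
    ax.set_title(f"$\\omega$ = {raster.omega:g}")
    return ax
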