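"""Simple figure helpers for trajectories, ensemble series, and tail fits.

Convenience plots for inspection, not faithful reproductions of any
particular figure layout.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trajectories", "plot_series", "plot_increment_histogram"]


def plot_trajectories(traj, ax=None, max_particles=50, **kwargs):
    """x(t) of up to ``max_particles`` pseudo-particles of one side."""
    if ax is None:
        _, ax = plt.subplots()
    t = traj.times_h()
    step = max(1, traj.n_particles // max_particles)
    for row in traj.x[::step]:
        ax.plot(t, row, lw=0.5, alpha=0.6, **kwargs)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("x position")
    ax.set_title(f"side {traj.side}, N={traj.n_particles}")
    return ax


def plot_series(time_h, values, label=None, ax=None, ylabel=None):
    """One ensemble series (mean position, velocity, ACF, MSD, ...)."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(time_h, values, marker=".", label=label)
    ax.set_xlabel("time or lag (h)")
    if ylabel:
        ax.set_ylabel(ylabel)
    if label:
        ax.legend()
    return ax


def plot_increment_histogram(abs_dv, fits=(), ax=None, bins="fd"):
    """|dV| histogram with optional fitted densities overlaid (log y-scale)."""
    if ax is None:
        _, ax = plt.subplots()
    abs_dv = np.asarray(abs_dv, dtype=float).ravel()
    ax.hist(abs_dv, bins=bins, density=True, alpha=0.4)
    grid = np.linspace(0, abs_dv.max(), 400)
    for fit in fits:
        if fit is None:
            continue
        if fit.model == "half_gaussian":
            s = fit.params["sigma"]
            ax.plot(grid, np.sqrt(2 / np.pi) / s * np.exp(-grid**2 / (2 * s**2)),
                    label=f"half-Gaussian σ={s:.3g}")
        elif fit.model == "exponential":
            lam = fit.params["lambda"]
            ax.plot(grid, np.exp(-grid / lam) / lam, "--",
                    label=f"exponential λ={lam:.3g}")
    ax.set_yscale("log")
    ax.set_xlabel("|ΔV|")
    ax.set_ylabel("density")
    ax.legend()
    return ax
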