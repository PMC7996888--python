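"""Ensemble SPT statistics on pseudo-particle trajectory matrices.

All statistics are ensemble averages over particles (rows); nothing here is
time-averaged.  The autocorrelation is the non-stationary ensemble ACF
anchored at t0 = 0: the correlation, across particles, between the variable
at time 0 and at lag tau, normalized by the two time-slice standard
deviations.  The mean squared value is likewise anchored at t0 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from woundtrack.errors import ValidationError
from woundtrack.pseudo_particles import TrajectoryMatrix

__all__ = [
    "center_initial_position",
    "mirror_right_front",
    "ensemble_mean",
    "velocity",
    "acceleration",
    "ensemble_acf",
    "mean_squared_displacement",
    "ensemble_std_series",
]


def center_initial_position(traj):
    """Shift x so the frame-0 ensemble mean is exactly zero (y untouched)."""
    shift = traj.x[:, 0].mean()
    return replace(traj, x=traj.x - shift, centered=True)


def mirror_right_front(traj, frame_width):
    """Mirror a right-front matrix (x -> frame_width - x) so it advances in +x."""
    if traj.side != "R":
        raise ValidationError("mirror_right_front applies only to the R side")
    return replace(traj, x=frame_width - traj.x, mirrored=not traj.mirrored)


def _as_matrix(values, min_cols=1, what="values"):
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"{what} must be a non-empty N x K matrix")
    if arr.shape[1] < min_cols:
        raise ValidationError(
            f"{what} needs at least {min_cols} columns, got {arr.shape[1]}"
        )
    return arr


def ensemble_mean(values):
    """Mean over particles: column means of an N x K matrix."""
    return _as_matrix(values).mean(axis=0)


def velocity(traj_x):
    """First differences along frames: position increments per sampling step."""
    arr = _as_matrix(traj_x, min_cols=2, what="positions")
    return np.diff(arr, axis=1)


def acceleration(vel):
    """First differences of the velocity (velocity increments)."""
    arr = _as_matrix(vel, min_cols=2, what="velocities")
    return np.diff(arr, axis=1)


def ensemble_acf(values, ddof=0):
    """Ensemble autocorrelation anchored at time 0.

    ACF(tau) = E[(Y(0) - mu_0)(Y(tau) - mu_tau)] / (sigma_0 sigma_tau),
    with moments taken across particles at fixed times.  Lags whose
    time-slice standard deviation vanishes are reported as NaN with a
    warning rather than raising.
    """
    arr = _as_matrix(values)
    n, k = arr.shape
    mu = arr.mean(axis=0)
    sigma = arr.std(axis=0, ddof=ddof)
    centered = arr - mu
    denom_n = n - ddof
    cov0 = centered[:, [0]] * centered  # (n, k)
    cov = cov0.sum(axis=0) / denom_n
    with np.errstate(divide="ignore", invalid="ignore"):
        acf = cov / (sigma[0] * sigma)
    bad = (sigma == 0) | (sigma[0] == 0)
    if np.any(bad):
        warnings.warn(
            "ensemble ACF undefined at lags with zero time-slice std; "
            "reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        acf = np.where(bad, np.nan, acf)
    return acf


def mean_squared_displacement(values):
    """MS(tau) = ensemble mean of (Y(tau) - Y(0))**2; MS(0) = 0."""
    arr = _as_matrix(values)
    disp = arr - arr[:, [0]]
    return (disp**2).mean(axis=0)


def ensemble_std_series(values, ddof=0):
    """Per-column ensemble standard deviation (population convention)."""
    arr = _as_matrix(values)
    if arr.shape[0] < 2:
        raise ValidationError("ensemble std needs at least 2 particles")
    return arr.std(axis=0, ddof=ddof)
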