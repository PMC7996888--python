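"""Uniform arc-length pseudo-particle sampling and trajectory assembly.

N points are placed on each front like pearls on a necklace: the polyline is
parameterized by cumulative chord length and resampled at n equally spaced
arc-length positions (endpoints included).  Particle identity across frames
is the arc-length rank, so column k of the trajectory matrix is simply the
resampling of the frame-k front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from woundtrack.errors import ValidationError

__all__ = [
    "TrajectoryMatrix",
    "sample_uniform_points",
    "build_trajectories",
    "wound_area_series",
]

DEFAULT_N_PARTICLES = 103


@dataclass
class TrajectoryMatrix:
    """N pseudo-particles x M frames of (x, y) positions for one wound side."""

    x: np.ndarray
    y: np.ndarray
    side: str
    frame_interval: float = 0.25
    pixel_size: float = 1.0
    mirrored: bool = False
    centered: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 2:
            raise ValidationError("x and y must be 2-D arrays of identical shape")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValidationError("trajectory matrices must not contain NaN")
        if self.side not in ("L", "R"):
            raise ValidationError(f"side must be 'L' or 'R', got {self.side!r}")

    @property
    def n_particles(self):
        return self.x.shape[0]

    @property
    def n_frames(self):
        return self.x.shape[1]

    def times_h(self):
        return np.arange(self.n_frames) * self.frame_interval


def sample_uniform_points(front, n):
    """n points uniformly spaced in arc length along a front polyline.

    Uses cumulative chord-length parameterization with linear interpolation
    of x(s) and y(s); sample i sits at s = i * L / (n - 1), endpoints
    included.
    """
    if n < 2:
        raise ValidationError("need at least 2 sample points")
    pts = np.asarray(front.points if hasattr(front, "points") else front, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValidationError("front needs an (n>=2, 2) point array")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValidationError("degenerate front: total arc length is zero")
    targets = np.linspace(0.0, total, n)
    xs = np.interp(targets, s, pts[:, 0])
    ys = np.interp(targets, s, pts[:, 1])
    return np.column_stack([xs, ys])


def build_trajectories(fronts, n=DEFAULT_N_PARTICLES, frame_interval=0.25,
                       pixel_size=1.0):
    """Assemble an N x M trajectory matrix from per-frame fronts of one side.

    ``fronts`` is a sequence of Front objects (same side) for M consecutive
    frames; a None entry marks a missing frame and is an error.
    """
    missing = [k for k, f in enumerate(fronts) if f is None]
    if missing:
        raise ValidationError(f"missing fronts for frames {missing}")
    if len(fronts) == 0:
        raise ValidationError("no fronts supplied")
    sides = {f.side for f in fronts}
    if len(sides) != 1:
        raise ValidationError(f"fronts mix sides {sorted(sides)}")
    cols = [sample_uniform_points(f, n) for f in fronts]
    stacked = np.stack(cols, axis=2)  # (n, 2, M)
    return TrajectoryMatrix(
        x=stacked[:, 0, :],
        y=stacked[:, 1, :],
        side=sides.pop(),
        frame_interval=frame_interval,
        pixel_size=pixel_size,
    )


def wound_area_series(fronts_l, fronts_r, normalize=True, frame_interval=0.25,
                      n_grid=2048):
    """Per-frame area enclosed between the L and R fronts.

    The fronts are interpolated as x(y) over their common y-range and the
    gap width max(0, x_R(y) - x_L(y)) is integrated by the trapezoid rule.
    If ``normalize``, the series is divided by the frame-0 area.
    """
    if len(fronts_l) != len(fronts_r):
        raise ValidationError("L and R front lists differ in length")
    areas = []
    for fl, fr in zip(fronts_l, fronts_r):
        nl, nr = fl.normalized(), fr.normalized()
        y_lo = max(nl.y.min(), nr.y.min())
        y_hi = min(nl.y.max(), nr.y.max())
        if y_hi <= y_lo:
            areas.append(0.0)
            continue
        grid = np.linspace(y_lo, y_hi, n_grid)
        gap = np.clip(np.interp(grid, nr.y, nr.x) - np.interp(grid, nl.y, nl.x),
                      0.0, None)
        areas.append(float(np.trapezoid(gap, grid)))
    areas = np.asarray(areas)
    if normalize:
        if areas.size == 0 or areas[0] <= 0:
            raise ValidationError("cannot normalize: frame-0 area is zero")
        areas = areas / areas[0]
    return areas
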