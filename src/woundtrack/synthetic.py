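"""Synthetic wound time-lapse generator with known ground truth.

Generates two textured cell layers separated by a smooth-background gap whose
fronts stay quiescent for ``lag_tau1`` frames and then advance toward each
other at ``drift_vd`` px/frame, with sinusoidal waviness and per-frame
Gaussian jitter.  Every random draw derives from the single spec-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from woundtrack.edge_extraction import Front
from woundtrack.errors import ValidationError
from woundtrack.frame_io import FrameStack

__all__ = [
    "SyntheticWoundSpec",
    "generate_ground_truth_fronts",
    "render_frames",
    "generate_dataset",
    "region_mask",
    "ground_truth_tile_labels",
]


@dataclass
class SyntheticWoundSpec:
    """Parameters of one synthetic wound-healing sequence.

    Drift is in px/frame and the quiescence lag in frames; the physical
    analogue follows from the frame interval chosen downstream.
    """

    height: int = 1200
    width: int = 1600
    n_frames: int = 40
    drift_vd: float = 4.0          # px/frame, per front
    lag_tau1: float = 8.0          # frames of quiescence before drift onset
    gap_fraction: float = 0.5      # initial gap width as fraction of frame width
    front_noise_sd: float = 1.0    # px, per-frame jitter of each front
    waviness_amplitude: float = 15.0   # px
    waviness_wavelength: float = 120.0  # px along y
    cell_mean: float = 130.0
    cell_contrast: float = 80.0    # bright/dark speckle swing
    grain_size: float = 2.5        # px, speckle grain scale
    cell_noise_sd: float = 10.0    # px-scale granularity inside the cell layer
    background_mean: float = 70.0
    background_noise_sd: float = 3.0
    background_smoothness: float = 4.0  # px, background noise smoothing
    halo_width: float = 2.0        # px, bright phase-contrast rim at the front
    halo_gain: float = 50.0
    global_noise_sd: float = 0.5
    frame_interval: float = 0.25   # h
    debris: bool = False           # textured islands inside the gap
    seed: int = 0

    def as_dict(self):
        return asdict(self)

    @property
    def initial_gap(self):
        return self.gap_fraction * self.width

    def closure_frame(self):
        """First frame at which the designed fronts could touch (worst case)."""
        margin = 2 * self.waviness_amplitude + 6 * self.front_noise_sd
        free = self.initial_gap - margin
        if self.drift_vd <= 0:
            return np.inf
        return self.lag_tau1 + free / (2.0 * self.drift_vd)

    def validate(self):
        if self.height < 8 or self.width < 8:
            raise ValidationError("frame too small")
        if self.n_frames < 1:
            raise ValidationError("need at least one frame")
        if not 0 < self.gap_fraction < 1:
            raise ValidationError("gap_fraction must lie in (0, 1)")
        closure = self.closure_frame()
        if closure < self.n_frames - 1:
            raise ValidationError(
                f"fronts would cross at frame ~{closure:.1f} "
                f"(< n_frames-1 = {self.n_frames - 1}); reduce drift_vd, "
                "waviness, or n_frames"
            )
        return self


def _front_rng(spec):
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))


def _render_rng(spec):
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))


def generate_ground_truth_fronts(spec):
    """Per-frame (Front L, Front R) ground-truth polylines, one point per row."""
    spec.validate()
    rng = _front_rng(spec)
    h, w = spec.height, spec.width
    y = np.arange(h, dtype=float)
    phase_l, phase_r = rng.uniform(0, 2 * np.pi, size=2)
    wav_l = spec.waviness_amplitude * np.sin(
        2 * np.pi * y / spec.waviness_wavelength + phase_l)
    wav_r = spec.waviness_amplitude * np.sin(
        2 * np.pi * y / spec.waviness_wavelength + phase_r)
    xl0 = (w - spec.initial_gap) / 2.0
    xr0 = (w + spec.initial_gap) / 2.0
    fronts = []
    for k in range(spec.n_frames):
        disp = spec.drift_vd * max(0.0, k - spec.lag_tau1)
        jl, jr = rng.normal(0.0, spec.front_noise_sd, size=2) \
            if spec.front_noise_sd > 0 else (0.0, 0.0)
        xl = np.clip(xl0 + disp + wav_l + jl, 1.0, w - 2.0)
        xr = np.clip(xr0 - disp + wav_r + jr, 1.0, w - 2.0)
        if np.any(xr - xl <= 0):
            raise ValidationError(f"realized fronts cross at frame {k}")
        fronts.append((
            Front(side="L", points=np.column_stack([xl, y]), frame_index=k),
            Front(side="R", points=np.column_stack([xr, y]), frame_index=k),
        ))
    return fronts


def _unit_sd_smooth_noise(rng, shape, smoothness):
    noise = rng.standard_normal(shape)
    if smoothness > 0:
        noise = ndimage.gaussian_filter(noise, smoothness)
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return noise


def region_mask(front_l, front_r, height, width):
    """Boolean ground-truth map: True where the cell layers are."""
    cols = np.arange(width, dtype=float)[None, :]
    xl = front_l.x_of_y(np.arange(height))[:, None]
    xr = front_r.x_of_y(np.arange(height))[:, None]
    return (cols < xl) | (cols > xr)


def render_frames(fronts, spec):
    """Render phase-contrast-like uint8 frames for the given fronts."""
    h, w = spec.height, spec.width
    rng = _render_rng(spec)
    cols = np.arange(w, dtype=float)[None, :]
    frames = []
    debris_centers = []
    if spec.debris:
        n_debris = max(1, (h * w) // 120000)
        debris_centers = [
            (rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.45 * w, 0.55 * w),
             rng.uniform(4, 10))
            for _ in range(n_debris)
        ]
    for k, (fl, fr) in enumerate(fronts):
        xl = fl.x_of_y(np.arange(h))[:, None]
        xr = fr.x_of_y(np.arange(h))[:, None]
        cell = (cols < xl) | (cols > xr)
        if spec.cell_contrast > 0:
            grain = _unit_sd_smooth_noise(rng, (h, w), spec.grain_size)
            speckle = spec.cell_mean + np.where(grain > 0, 0.5, -0.5) * spec.cell_contrast
        else:
            speckle = np.full((h, w), spec.cell_mean, dtype=float)
        if spec.cell_noise_sd > 0:
            speckle = speckle + rng.normal(0.0, spec.cell_noise_sd, size=(h, w))
        if spec.background_noise_sd > 0:
            bg = spec.background_mean + spec.background_noise_sd * \
                _unit_sd_smooth_noise(rng, (h, w), spec.background_smoothness)
        else:
            bg = np.full((h, w), spec.background_mean)
        img = np.where(cell, speckle, bg)
        if spec.halo_width > 0 and spec.halo_gain != 0:
            near = (np.abs(cols - xl) <= spec.halo_width) | \
                   (np.abs(cols - xr) <= spec.halo_width)
            img = img + near * spec.halo_gain
        for (cy, cx, r) in debris_centers:
            yy, xx = np.ogrid[:h, :w]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            img = np.where(blob & ~cell, speckle, img)
        if spec.global_noise_sd > 0:
            img = img + rng.normal(0.0, spec.global_noise_sd, size=(h, w))
        frames.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
    return FrameStack(frames=frames, frame_interval=spec.frame_interval)


def generate_dataset(spec):
    """Convenience: ground-truth fronts plus rendered frames for one spec."""
    fronts = generate_ground_truth_fronts(spec)
    stack = render_frames(fronts, spec)
    return stack, fronts


def ground_truth_tile_labels(front_l, front_r, grid, height, width):
    """Majority cell/background label per tile of the ground-truth region map."""
    mask = region_mask(front_l, front_r, height, width)
    ch, cw = grid.covered_shape
    th, tw = grid.tile_height, grid.tile_width
    tiles = mask[:ch, :cw].reshape(grid.n_rows, th, grid.n_cols, tw)
    frac = tiles.mean(axis=(1, 3))
    return (frac >= 0.5).astype(int).ravel()
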