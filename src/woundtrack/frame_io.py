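"""Loading, validation, and contrast equalization of time-lapse frames.

Frames are single-channel integer images.  CLAHE (contrast-limited adaptive
histogram equalization) is implemented with the tile size given in pixels and
the clip limit given in histogram counts per bin; excess counts above the clip
limit are redistributed uniformly over all bins before the per-tile histogram
equalization, and per-pixel mappings are bilinearly interpolated between
neighbouring tile mappings to suppress tile seams.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

from woundtrack.errors import InputError, ValidationError

__all__ = ["FrameStack", "load_time_lapse", "equalize_frame", "equalize_stack"]

#: RGB -> luminance weights (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_FRAME_INTERVAL_H = 0.25
DEFAULT_CLAHE_TILE = (50, 50)
DEFAULT_CLAHE_CLIP = 40.0


@dataclass
class FrameStack:
    """An ordered time-lapse of same-sized grayscale frames.

    Parameters
    ----------
    frames
        List of 2-D integer arrays, one per acquisition time.
    frame_interval
        Hours between consecutive frames (default 0.25 h, i.e. 4 frames/hour).
    pixel_size
        Micrometres per pixel.  Defaults to 1.0, in which case downstream
        positions stay in pixel units.
    """

    frames: list = field(default_factory=list)
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H
    pixel_size: float = 1.0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        frames = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f)
            if f.ndim == 3:
                f = to_grayscale(f)
            if f.ndim != 2:
                raise ValidationError(f"frame {i} is not 2-D (shape {f.shape})")
            frames.append(f)
        self.frames = frames
        if frames:
            h, w = frames[0].shape
            for i, f in enumerate(frames):
                if f.shape != (h, w):
                    raise ValidationError(
                        f"frame {i} has shape {f.shape}, expected {(h, w)}"
                    )

    def __len__(self):
        return len(self.frames)

    def __getitem__(self, k):
        return self.frames[k]

    def __iter__(self):
        return iter(self.frames)

    @property
    def height(self):
        return self.frames[0].shape[0] if self.frames else 0

    @property
    def width(self):
        return self.frames[0].shape[1] if self.frames else 0

    def times_h(self):
        """Acquisition time of each frame in hours."""
        return np.arange(len(self.frames)) * self.frame_interval

    def subset(self, start=0, stop=None, stride=1):
        """Frame-range/stride selection; returns a new stack sharing arrays."""
        return FrameStack(
            frames=self.frames[start:stop:stride],
            frame_interval=self.frame_interval * stride,
            pixel_size=self.pixel_size,
        )


def to_grayscale(frame):
    """Reduce an (H, W, C) frame to single-channel luminance, keeping dtype."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim != 3:
        raise ValidationError(f"expected 2-D or 3-D frame, got shape {frame.shape}")
    c = frame.shape[2]
    if c == 1:
        return frame[:, :, 0]
    gray = frame[:, :, :3].astype(float) @ _LUMA
    if np.issubdtype(frame.dtype, np.integer):
        return np.round(gray).astype(frame.dtype)
    return gray


_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


def load_time_lapse(path, frame_interval=DEFAULT_FRAME_INTERVAL_H, pixel_size=1.0):
    """Load a multi-page TIFF or a directory of frames as a :class:`FrameStack`.

    Directory frames are ordered lexicographically by filename (= time order).
    RGB input is converted to grayscale by luminance.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    if path.is_dir():
        names = sorted(
            p for p in os.listdir(path)
            if (path / p).is_file() and Path(p).suffix.lower() in _FRAME_SUFFIXES
        )
        if not names:
            raise InputError(f"directory contains no .tif/.tiff/.png frames: {path}")
        frames = []
        shape0 = None
        for name in names:
            try:
                arr = iio.imread(path / name)
            except Exception as exc:  # noqa: BLE001 - report the offending file
                raise InputError(f"unreadable frame {name}: {exc}") from exc
            arr = to_grayscale(arr)
            if shape0 is None:
                shape0 = arr.shape
            elif arr.shape != shape0:
                raise ValidationError(
                    f"frame {name} has shape {arr.shape}, expected {shape0}"
                )
            frames.append(arr)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise InputError(f"unreadable TIFF {path}: {exc}") from exc
        arr = np.asarray(arr)
        if arr.ndim == 2:
            frames = [arr]
        elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            frames = [to_grayscale(arr)]
        elif arr.ndim == 3:
            frames = [arr[k] for k in range(arr.shape[0])]
        elif arr.ndim == 4:
            frames = [to_grayscale(arr[k]) for k in range(arr.shape[0])]
        else:
            raise ValidationError(f"unsupported TIFF dimensionality {arr.shape}")
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValidationError(f"mixed frame dimensions in stack: {sorted(shapes)}")
    return FrameStack(frames=frames, frame_interval=frame_interval, pixel_size=pixel_size)


def _n_levels(dtype):
    if np.issubdtype(dtype, np.integer):
        return int(np.iinfo(dtype).max) + 1
    return 256


def _tile_mapping(tile, n_levels, clip_limit, full_tile_area=None):
    """Clipped-histogram equalization LUT for one tile (levels -> levels).

    ``clip_limit`` is a count per bin for a full-size tile; partial border
    tiles clip at the proportionally scaled count so identical content maps
    identically regardless of tile area.
    """
    hist = np.bincount(tile.ravel(), minlength=n_levels).astype(float)
    if clip_limit is not None and clip_limit > 0:
        clip = clip_limit
        if full_tile_area:
            clip = clip_limit * tile.size / full_tile_area
        excess = np.clip(hist - clip, 0, None).sum()
        hist = np.minimum(hist, clip)
        hist += excess / n_levels
    cdf = np.cumsum(hist)
    n = cdf[-1]
    cdf_min = cdf[np.argmax(hist > 0)] if np.any(hist > 0) else 0.0
    denom = n - cdf_min
    if denom <= 0:
        # degenerate tile (all mass in the first occupied bin and no
        # redistribution): identity mapping keeps the frame constant
        return np.arange(n_levels, dtype=float)
    return (cdf - cdf_min) / denom * (n_levels - 1)


def equalize_frame(frame, tile_size=DEFAULT_CLAHE_TILE, clip_limit=DEFAULT_CLAHE_CLIP):
    """CLAHE of a single grayscale frame.

    Parameters
    ----------
    frame
        2-D integer array.
    tile_size
        (rows, cols) tile extent in pixels.  Partial border tiles are
        equalized as-is.
    clip_limit
        Maximum histogram count per bin before redistribution; ``None``
        disables clipping (plain per-tile equalization).

    Returns
    -------
    ndarray
        Equalized frame, same shape and dtype as the input.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValidationError("equalize_frame expects a single-channel 2-D frame")
    th, tw = int(tile_size[0]), int(tile_size[1])
    H, W = frame.shape
    if th <= 0 or tw <= 0:
        raise ValidationError("tile_size entries must be positive")
    if th > H or tw > W:
        raise ValidationError(
            f"tile_size {(th, tw)} larger than frame {(H, W)}"
        )
    if not np.issubdtype(frame.dtype, np.integer):
        raise ValidationError("equalize_frame expects integer intensities")
    if frame.min() < 0:
        raise ValidationError("negative intensities are not supported")

    n_levels = _n_levels(frame.dtype)
    work = frame.astype(np.int64)

    n_rows = int(np.ceil(H / th))
    n_cols = int(np.ceil(W / tw))

    # per-tile LUTs and tile centres
    luts = np.empty((n_rows, n_cols, n_levels), dtype=float)
    row_centers = np.empty(n_rows)
    col_centers = np.empty(n_cols)
    for r in range(n_rows):
        r0, r1 = r * th, min((r + 1) * th, H)
        row_centers[r] = (r0 + r1 - 1) / 2.0
        for c in range(n_cols):
            c0, c1 = c * tw, min((c + 1) * tw, W)
            if r == 0:
                col_centers[c] = (c0 + c1 - 1) / 2.0
            luts[r, c] = _tile_mapping(
                work[r0:r1, c0:c1], n_levels, clip_limit, full_tile_area=th * tw
            )

    # bilinear interpolation between the four surrounding tile mappings
    rows = np.arange(H, dtype=float)
    cols = np.arange(W, dtype=float)
    ri = np.clip(np.searchsorted(row_centers, rows) - 1, 0, max(n_rows - 2, 0))
    ci = np.clip(np.searchsorted(col_centers, cols) - 1, 0, max(n_cols - 2, 0))
    if n_rows > 1:
        fr = (rows - row_centers[ri]) / (row_centers[ri + 1] - row_centers[ri])
        fr = np.clip(fr, 0.0, 1.0)
    else:
        fr = np.zeros(H)
    if n_cols > 1:
        fc = (cols - col_centers[ci]) / (col_centers[ci + 1] - col_centers[ci])
        fc = np.clip(fc, 0.0, 1.0)
    else:
        fc = np.zeros(W)

    ri2 = np.minimum(ri + 1, n_rows - 1)
    ci2 = np.minimum(ci + 1, n_cols - 1)
    RI, CI = np.meshgrid(ri, ci, indexing="ij")
    RI2, CI2 = np.meshgrid(ri2, ci2, indexing="ij")
    FR, FC = np.meshgrid(fr, fc, indexing="ij")

    v = work
    tl = luts[RI, CI, v]
    tr = luts[RI, CI2, v]
    bl = luts[RI2, CI, v]
    br = luts[RI2, CI2, v]
    out = (1 - FR) * ((1 - FC) * tl + FC * tr) + FR * ((1 - FC) * bl + FC * br)
    return np.clip(np.round(out), 0, n_levels - 1).astype(frame.dtype)


def equalize_stack(stack, tile_size=DEFAULT_CLAHE_TILE, clip_limit=DEFAULT_CLAHE_CLIP):
    """Apply :func:`equalize_frame` to every frame of a stack."""
    return FrameStack(
        frames=[equalize_frame(f, tile_size, clip_limit) for f in stack.frames],
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
    )


def write_stack(stack, path):
    """Write a stack as a multi-page TIFF for inspection."""
    tifffile.imwrite(path, np.stack([np.asarray(f) for f in stack.frames]))
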