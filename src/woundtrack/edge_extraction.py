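"""Wound-front extraction from binary masks, Otsu baseline, and front I/O.

Coordinates follow the image convention: ``x`` = column, ``y`` = row,
0-based, y increasing downward.  The wound is the longest boundary contour
(by arc length) between cell and background regions; it is split at the top
and bottom image borders into the left (L) and right (R) fronts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import filters, measure, morphology

from woundtrack.errors import InputError, SegmentationError, ValidationError
from woundtrack.texture_segmentation import BinaryMask

__all__ = [
    "Front",
    "ContourSet",
    "extract_wound_contour",
    "split_fronts",
    "otsu_threshold",
    "otsu_segment",
    "read_imagej_front",
    "write_front",
]

logger = logging.getLogger(__name__)


@dataclass
class Front:
    """One wound edge in one frame: an ordered polyline of (x, y) points."""

    side: str  # "L" or "R"
    points: np.ndarray  # (n, 2) float array of (x, y)
    frame_index: int = 0

    def __post_init__(self):
        if self.side not in ("L", "R"):
            raise ValidationError(f"side must be 'L' or 'R', got {self.side!r}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValidationError("a front needs an (n>=2, 2) point array")
        # drop consecutive duplicates
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
        pts = pts[keep]
        if len(pts) < 2:
            raise ValidationError("front collapses to fewer than 2 distinct points")
        self.points = pts

    @property
    def x(self):
        return self.points[:, 0]

    @property
    def y(self):
        return self.points[:, 1]

    def length(self):
        """Total arc length of the polyline."""
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def normalized(self):
        """Copy with points ordered by strictly increasing y.

        Points are stably sorted by y; runs of equal y are collapsed to a
        single point at their mean x, so the result can be read as x(y).
        """
        order = np.argsort(self.points[:, 1], kind="stable")
        pts = self.points[order]
        ys, inverse = np.unique(pts[:, 1], return_inverse=True)
        if len(ys) < 2:
            raise ValidationError("front is degenerate after y-normalization")
        xs = np.bincount(inverse, weights=pts[:, 0]) / np.bincount(inverse)
        return replace(self, points=np.column_stack([xs, ys]))

    def x_of_y(self, y_query):
        """Interpolated x-position at the requested y values (normalized view)."""
        norm = self.normalized()
        return np.interp(np.asarray(y_query, dtype=float), norm.y, norm.x)


@dataclass
class ContourSet:
    """All cell/background boundary contours of one mask, wound flagged."""

    contours: list = field(default_factory=list)  # (n, 2) arrays of (x, y)
    lengths: np.ndarray = None
    wound_index: int = -1
    frame_shape: tuple = (0, 0)
    frame_index: int = 0

    @property
    def wound(self):
        return self.contours[self.wound_index]


def _closed_arc_length(contour_xy):
    d = np.diff(contour_xy, axis=0)
    length = float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    if not np.array_equal(contour_xy[0], contour_xy[-1]):
        length += float(np.hypot(*(contour_xy[0] - contour_xy[-1])))
    return length


def extract_wound_contour(mask, frame_index=None):
    """Trace all boundary contours of a mask and flag the longest as the wound.

    The mask is padded with cell (True) so contours touching the frame border
    are closed along the border; lengths therefore include the border closure.
    """
    if isinstance(mask, BinaryMask):
        arr = mask.mask
        if frame_index is None:
            frame_index = mask.frame_index
    else:
        arr = np.asarray(mask, dtype=bool)
    frame_index = frame_index or 0
    if arr.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if arr.all() or not arr.any():
        raise SegmentationError(
            f"no wound detected in frame {frame_index}: mask is uniform"
        )
    padded = np.pad(arr, 1, mode="constant", constant_values=True).astype(float)
    raw = measure.find_contours(padded, 0.5)
    contours = []
    for c in raw:
        # (row, col) in padded coords -> (x, y) in frame coords
        xy = np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0])
        contours.append(xy)
    if not contours:
        raise SegmentationError(f"no contours found in frame {frame_index}")
    lengths = np.array([_closed_arc_length(c) for c in contours])
    return ContourSet(
        contours=contours,
        lengths=lengths,
        wound_index=int(np.argmax(lengths)),
        frame_shape=arr.shape,
        frame_index=frame_index,
    )


def split_fronts(wound_contour, frame_width, frame_height=None, frame_index=0):
    """Cut the wound contour at the top/bottom borders into L and R fronts.

    The wound contour must span the frame vertically (scratch geometry).  The
    closed contour is split by removing its runs along the top and bottom
    borders; the remaining two arcs are the fronts.  The arc with smaller
    mean x becomes L, the other R; both are reordered to increasing y.
    """
    if isinstance(wound_contour, ContourSet):
        if frame_height is None:
            frame_height = wound_contour.frame_shape[0]
        frame_index = wound_contour.frame_index
        wound_contour = wound_contour.wound
    pts = np.asarray(wound_contour, dtype=float)
    if len(pts) and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if frame_height is None:
        frame_height = int(np.ceil(pts[:, 1].max()))
    top, bottom = 0.0, float(frame_height - 1)
    if pts[:, 1].min() >= top or pts[:, 1].max() <= bottom:
        raise SegmentationError(
            f"fronts merged or detached in frame {frame_index}: wound contour "
            "does not span the frame top-to-bottom"
        )
    interior = (pts[:, 1] >= top) & (pts[:, 1] <= bottom)
    # contiguous runs of interior points on the cyclic sequence
    idx = np.flatnonzero(interior)
    if idx.size < 4:
        raise SegmentationError(f"wound contour degenerate in frame {frame_index}")
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    if not interior[0] or not interior[-1]:
        pass  # runs already correct on the linear sequence
    elif len(runs) > 1:
        # cyclic wrap: first and last run are one
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs = runs[:-1]
    # a true front arc runs border to border; stray arcs from mask noise
    # touch only one border and are discarded
    spanning = [r for r in runs
                if pts[r, 1].min() <= top + 1 and pts[r, 1].max() >= bottom - 1]
    if len(spanning) < 2:
        raise SegmentationError(
            f"fronts merged or detached in frame {frame_index}: found "
            f"{len(spanning)} border-spanning front arcs instead of 2"
        )
    if len(spanning) > 2:
        logger.warning(
            "frame %d: %d border-spanning arcs, keeping the two longest",
            frame_index, len(spanning),
        )
        spanning = sorted(
            spanning,
            key=lambda r: float(np.sum(np.hypot(*np.diff(pts[r], axis=0).T))),
            reverse=True,
        )[:2]
    arcs = [np.clip(pts[r], [0.0, top], [frame_width - 1.0, bottom])
            for r in spanning]
    means = [a[:, 0].mean() for a in arcs]
    left, right = (arcs[0], arcs[1]) if means[0] <= means[1] else (arcs[1], arcs[0])
    front_l = Front(side="L", points=left, frame_index=frame_index).normalized()
    front_r = Front(side="R", points=right, frame_index=frame_index).normalized()
    return front_l, front_r


def otsu_threshold(frame):
    """Global Otsu threshold (maximizes between-class variance).

    Returns a threshold ``t`` such that the foreground is ``frame > t``.
    """
    frame = np.asarray(frame)
    if frame.min() == frame.max():
        raise SegmentationError("Otsu threshold undefined for a constant frame")
    return filters.threshold_otsu(frame)


def otsu_segment(frame, blur_sigma=2.0, morph_radius=5, cell_brighter=True,
                 frame_index=0):
    """Otsu baseline segmentation: Gaussian blur, Otsu, closing then opening.

    The caller is expected to pass an already contrast-equalized frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError("otsu_segment expects a 2-D frame")
    blurred = filters.gaussian(frame, sigma=blur_sigma, preserve_range=True)
    thr = otsu_threshold(blurred)
    mask = blurred > thr if cell_brighter else blurred <= thr
    if morph_radius and morph_radius > 0:
        footprint = morphology.disk(int(morph_radius))
        mask = morphology.closing(mask, footprint)
        mask = morphology.opening(mask, footprint)
    return BinaryMask(mask=mask, frame_index=frame_index)


def read_imagej_front(path, side, frame_index=0):
    """Read a hand-traced front from a plain-text file of one point per line.

    Accepts whitespace- or comma-separated "x y" pairs.  The result is
    normalized to increasing y.
    """
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) < 2:
                raise InputError(f"{path}: line {lineno}: expected 'x y', got {line!r}")
            try:
                x, y = float(tokens[0]), float(tokens[1])
            except ValueError as exc:
                raise InputError(
                    f"{path}: line {lineno}: non-numeric token in {line!r}"
                ) from exc
            points.append((x, y))
    if len(points) < 2:
        raise ValidationError(f"{path}: front needs at least 2 points, got {len(points)}")
    return Front(side=side, points=np.array(points), frame_index=frame_index).normalized()


def write_front(front, path):
    """Write a front in the same plain-text "x y" dialect."""
    np.savetxt(path, front.points, fmt="%.6g")
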