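"""Tile-level texture classification of frames into cell layer vs background.

Each pixel gets a local-binary-pattern (LBP) *count*: the number of its 8
neighbours for which center >= neighbour, in {0..8} (this is the count
variant, not the classical weighted 8-bit code).  Frames are tessellated into
non-overlapping tiles, each tile is summarized by its 9-bin LBP frequency
histogram, and tiles are clustered into two groups with PCA followed by a
2-component Gaussian mixture.  Tile labels broadcast to pixels give the
binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from woundtrack.errors import FitError, ValidationError

__all__ = [
    "TileGrid",
    "TextureClassifier",
    "BinaryMask",
    "lbp_image",
    "tessellate",
    "lbp_histogram",
    "extract_features",
    "fit_texture_classifier",
    "binarize_frame",
]

DEFAULT_TILE_HEIGHT = 12
DEFAULT_TILE_WIDTH = 16
N_LBP_BINS = 9  # scores 0..8


def lbp_image(frame):
    """Per-pixel LBP count image.

    For each pixel, the value is the number of its 8 neighbours ``nb`` with
    ``center >= nb`` (ties count).  The frame is replicate-padded by one pixel
    so border pixels get a full neighbourhood and the output has the frame's
    shape.  Values lie in {0..8}.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValidationError("lbp_image expects a 2-D frame")
    if frame.shape[0] < 3 or frame.shape[1] < 3:
        raise ValidationError(f"frame too small for 3x3 LBP: {frame.shape}")
    p = np.pad(frame, 1, mode="edge")
    c = p[1:-1, 1:-1]
    out = np.zeros(frame.shape, dtype=np.uint8)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = p[1 + dr : p.shape[0] - 1 + dr, 1 + dc : p.shape[1] - 1 + dc]
            out += (c >= nb).astype(np.uint8)
    return out


@dataclass(frozen=True)
class TileGrid:
    """Row-major grid of non-overlapping tiles covering (part of) a frame.

    ``n_rows = floor(H / tile_height)``; any remainder strip at the bottom or
    right border is dropped and recorded via :attr:`covered_shape`.
    """

    tile_height: int = DEFAULT_TILE_HEIGHT
    tile_width: int = DEFAULT_TILE_WIDTH
    n_rows: int = 0
    n_cols: int = 0

    @property
    def n_tiles(self):
        return self.n_rows * self.n_cols

    @property
    def covered_shape(self):
        return (self.n_rows * self.tile_height, self.n_cols * self.tile_width)

    def tile_index(self, row, col):
        return row * self.n_cols + col

    def tile_position(self, index):
        return divmod(index, self.n_cols)

    def tile_slices(self, index):
        r, c = self.tile_position(index)
        return (
            slice(r * self.tile_height, (r + 1) * self.tile_height),
            slice(c * self.tile_width, (c + 1) * self.tile_width),
        )


def tessellate(frame, tile_height=DEFAULT_TILE_HEIGHT, tile_width=DEFAULT_TILE_WIDTH):
    """Tessellate a frame into a :class:`TileGrid` of fixed-size tiles."""
    frame = np.asarray(frame)
    H, W = frame.shape[:2]
    if tile_height <= 0 or tile_width <= 0:
        raise ValidationError("tile dimensions must be positive")
    if tile_height > H or tile_width > W:
        raise ValidationError(
            f"tile {(tile_height, tile_width)} larger than frame {(H, W)}"
        )
    return TileGrid(
        tile_height=tile_height,
        tile_width=tile_width,
        n_rows=H // tile_height,
        n_cols=W // tile_width,
    )


def lbp_histogram(lbp_tile):
    """9-bin frequency vector of the LBP scores in one tile (sums to 1)."""
    lbp_tile = np.asarray(lbp_tile)
    if lbp_tile.size == 0:
        raise ValidationError("empty tile")
    if lbp_tile.min() < 0 or lbp_tile.max() > 8:
        raise ValidationError("LBP scores must lie in {0..8}")
    counts = np.bincount(lbp_tile.ravel().astype(np.int64), minlength=N_LBP_BINS)
    return counts / lbp_tile.size


def extract_features(lbp, grid):
    """Per-tile LBP histograms as an (n_tiles, 9) matrix in row-major order."""
    lbp = np.asarray(lbp)
    ch, cw = grid.covered_shape
    if lbp.shape[0] < ch or lbp.shape[1] < cw:
        raise ValidationError(
            f"grid covers {(ch, cw)} but LBP image is {lbp.shape}"
        )
    th, tw = grid.tile_height, grid.tile_width
    # reshape to (n_rows, th, n_cols, tw) then histogram each tile
    tiles = lbp[:ch, :cw].reshape(grid.n_rows, th, grid.n_cols, tw)
    tiles = tiles.transpose(0, 2, 1, 3).reshape(grid.n_tiles, th * tw)
    feats = np.zeros((grid.n_tiles, N_LBP_BINS))
    offset = np.arange(grid.n_tiles) * N_LBP_BINS
    flat = np.bincount(
        (tiles.astype(np.int64) + offset[:, None]).ravel(),
        minlength=grid.n_tiles * N_LBP_BINS,
    )
    feats = flat.reshape(grid.n_tiles, N_LBP_BINS) / (th * tw)
    return feats


@dataclass
class TextureClassifier:
    """PCA + 2-component Gaussian mixture over tile LBP histograms.

    ``label_map[component] in {0, 1}`` resolves mixture components to
    semantic labels (1 = cell layer, 0 = background).
    """

    n_pca: int = 5
    seed: int = 0
    covariance_type: str = "full"
    n_init: int = 5  # EM restarts; single k-means++ init lands in bad optima
    labeling: str = "auto"  # "auto" | "component0_is_cell" | "component1_is_cell"
    pca: PCA | None = field(default=None, repr=False)
    gmm: GaussianMixture | None = field(default=None, repr=False)
    label_map: dict | None = None

    @property
    def fitted(self):
        return self.pca is not None and self.gmm is not None

    def fit(self, features):
        features = np.asarray(features, dtype=float)
        if not np.all(np.isfinite(features)):
            raise ValidationError("features must be finite")
        n_tiles = features.shape[0]
        if n_tiles < 2 * self.n_pca:
            raise ValidationError(
                f"need at least {2 * self.n_pca} tiles, got {n_tiles}"
            )
        if np.allclose(features.std(axis=0), 0.0):
            raise FitError(
                "degenerate features: zero variance in every dimension "
                "(uniform texture; nothing to separate)"
            )
        self.pca = PCA(n_components=self.n_pca, random_state=self.seed)
        scores = self.pca.fit_transform(features)
        self.gmm = GaussianMixture(
            n_components=2,
            covariance_type=self.covariance_type,
            random_state=self.seed,
            max_iter=200,
            tol=1e-4,
            n_init=self.n_init,
            init_params="k-means++",
        )
        self.gmm.fit(scores)
        self._resolve_labels(features, self.gmm.predict(scores))
        return self

    def _resolve_labels(self, features, components):
        if self.labeling == "component0_is_cell":
            self.label_map = {0: 1, 1: 0}
        elif self.labeling == "component1_is_cell":
            self.label_map = {0: 0, 1: 1}
        elif self.labeling == "auto":
            # phase-contrast background is smoother than the cell layer, so
            # its LBP histograms are more concentrated: the component with
            # the lower mean per-tile histogram entropy is background
            with np.errstate(divide="ignore", invalid="ignore"):
                per_tile = -np.nansum(
                    np.where(features > 0, features * np.log(features), 0.0),
                    axis=1,
                )
            ent = [per_tile[components == c].mean() if np.any(components == c)
                   else np.inf for c in (0, 1)]
            bg = int(np.argmin(ent))
            self.label_map = {bg: 0, 1 - bg: 1}
        elif self.labeling == "flat8":
            # alternative rule: larger mean frequency of the flat-texture
            # score LBP=8 marks the background
            flat8 = [features[components == c, 8].mean() if np.any(components == c)
                     else 0.0 for c in (0, 1)]
            bg = int(np.argmax(flat8))
            self.label_map = {bg: 0, 1 - bg: 1}
        else:
            raise ValidationError(f"unknown labeling mode: {self.labeling!r}")

    def predict(self, features):
        """Semantic labels (1 = cell) for feature rows."""
        if not self.fitted:
            raise ValidationError("classifier is not fitted")
        comps = self.gmm.predict(self.pca.transform(np.asarray(features, dtype=float)))
        lut = np.array([self.label_map[0], self.label_map[1]])
        return lut[comps]


def fit_texture_classifier(features, n_pca=5, seed=0, covariance_type="full",
                           labeling="auto", n_init=5):
    """Fit PCA + GMM on an (n_tiles, 9) LBP-histogram matrix.

    Deterministic for a fixed ``seed``.
    """
    clf = TextureClassifier(
        n_pca=n_pca, seed=seed, covariance_type=covariance_type,
        labeling=labeling, n_init=n_init,
    )
    return clf.fit(features)


@dataclass
class BinaryMask:
    """Frame-resolution boolean mask; True = cell layer."""

    mask: np.ndarray
    frame_index: int = 0
    grid: TileGrid | None = None

    @property
    def shape(self):
        return self.mask.shape


def binarize_frame(frame, classifier, grid, frame_index=0):
    """Classify every tile of a frame and broadcast labels to pixels."""
    if not classifier.fitted:
        raise ValidationError("classifier is not fitted")
    frame = np.asarray(frame)
    ch, cw = grid.covered_shape
    if frame.shape[0] < ch or frame.shape[1] < cw:
        raise ValidationError(f"grid covers {(ch, cw)} but frame is {frame.shape}")
    feats = extract_features(lbp_image(frame), grid)
    labels = classifier.predict(feats).reshape(grid.n_rows, grid.n_cols)
    mask = np.repeat(np.repeat(labels, grid.tile_height, axis=0),
                     grid.tile_width, axis=1).astype(bool)
    return BinaryMask(mask=mask, frame_index=frame_index, grid=grid)
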