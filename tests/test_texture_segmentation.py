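import numpy as np
import pytest
from scipy import ndimage

from woundtrack.errors import FitError, ValidationError
from woundtrack.texture_segmentation import (
    binarize_frame,
    extract_features,
    fit_texture_classifier,
    lbp_histogram,
    lbp_image,
    tessellate,
)


def naive_lbp(frame):
    """Oracle: per-pixel loop over the 8 neighbours on a replicate-padded frame."""
    p = np.pad(frame, 1, mode="edge").astype(float)
    h, w = frame.shape
    out = np.zeros((h, w), dtype=int)
    for i in range(h):
        for j in range(w):
            c = p[i + 1, j + 1]
            score = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    if c >= p[i + 1 + di, j + 1 + dj]:
                        score += 1
            out[i, j] = score
    return out


def two_texture_frame(rng, height=120, width=160):
    """Left half: smooth gradient; right half: salt-and-pepper."""
    frame = np.zeros((height, width))
    frame[:, : width // 2] = np.linspace(40, 90, width // 2)[None, :]
    frame[:, : width // 2] += ndimage.gaussian_filter(
        rng.standard_normal((height, width // 2)), 4
    )
    frame[:, width // 2 :] = rng.choice([30, 220], size=(height, width - width // 2))
    return np.clip(np.round(frame), 0, 255).astype(np.uint8)


class TestLbpImage:
    def test_constant_frame_all_eight(self):
        assert np.all(lbp_image(np.full((5, 7), 9)) == 8)

    def test_strict_local_minimum_zero(self):
        frame = np.full((5, 5), 10)
        frame[2, 2] = 1
        assert lbp_image(frame)[2, 2] == 0

    def test_checkerboard(self):
        # 0-pixels see four 1-valued edge neighbours (fail) and four 0-valued
        # diagonals (ties) -> 4; 1-pixels are >= all 8 neighbours -> 8
        frame = np.indices((6, 6)).sum(axis=0) % 2
        lbp = lbp_image(frame)
        interior = lbp[1:-1, 1:-1]
        zeros = frame[1:-1, 1:-1] == 0
        assert np.all(interior[zeros] == 4)
        assert np.all(interior[~zeros] == 8)

    def test_matches_naive_oracle(self, rng):
        frame = rng.integers(0, 10, (12, 9))
        assert np.array_equal(lbp_image(frame), naive_lbp(frame))

    def test_range(self, rng):
        lbp = lbp_image(rng.integers(0, 255, (30, 30)))
        assert lbp.min() >= 0 and lbp.max() <= 8

    def test_monotone_transform_invariance(self, rng):
        frame = rng.integers(0, 100, (20, 20))
        transformed = (3 * frame.astype(np.int64) ** 2 + 7)  # strictly increasing on >=0
        assert np.array_equal(lbp_image(frame), lbp_image(transformed))

    def test_too_small(self):
        with pytest.raises(ValidationError):
            lbp_image(np.zeros((2, 5)))


class TestTessellate:
    def test_paper_geometry(self):
        grid = tessellate(np.zeros((1200, 1600)), 12, 16)
        assert grid.n_rows == 100 and grid.n_cols == 100
        assert grid.n_tiles == 10_000

    def test_single_tile(self):
        assert tessellate(np.zeros((12, 16)), 12, 16).n_tiles == 1

    def test_two_by_two(self):
        assert tessellate(np.zeros((24, 32)), 12, 16).n_tiles == 4

    def test_remainder_dropped(self):
        grid = tessellate(np.zeros((25, 33)), 12, 16)
        assert (grid.n_rows, grid.n_cols) == (2, 2)
        assert grid.covered_shape == (24, 32)

    def test_tile_larger_than_frame(self):
        with pytest.raises(ValidationError):
            tessellate(np.zeros((10, 10)), 12, 16)

    def test_index_round_trip(self):
        grid = tessellate(np.zeros((24, 48)), 12, 16)
        for idx in range(grid.n_tiles):
            assert grid.tile_index(*grid.tile_position(idx)) == idx


class TestLbpHistogram:
    def test_all_eights(self):
        hist = lbp_histogram(np.full((12, 16), 8))
        assert np.array_equal(hist, np.eye(9)[8])

    def test_half_zero_half_eight(self):
        tile = np.array([[0, 8], [8, 0]])
        hist = lbp_histogram(tile)
        assert hist[0] == 0.5 and hist[8] == 0.5

    def test_matches_counting_oracle(self, rng):
        tile = rng.integers(0, 9, (12, 16))
        hist = lbp_histogram(tile)
        for b in range(9):
            count = sum(1 for v in tile.ravel() if v == b)
            assert hist[b] == pytest.approx(count / tile.size)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_tile(self):
        with pytest.raises(ValidationError):
            lbp_histogram(np.zeros((0, 4)))

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            lbp_histogram(np.full((2, 2), 9))


class TestExtractFeatures:
    def test_paper_shape(self):
        frame = np.zeros((1200, 1600), dtype=np.uint8)
        grid = tessellate(frame, 12, 16)
        feats = extract_features(lbp_image(frame), grid)
        assert feats.shape == (10_000, 9)

    def test_constant_frame_rows(self):
        frame = np.full((24, 32), 5)
        feats = extract_features(lbp_image(frame), grid := tessellate(frame, 12, 16))
        assert np.allclose(feats, np.tile(np.eye(9)[8], (grid.n_tiles, 1)))

    def test_rows_are_probability_vectors(self, rng):
        frame = rng.integers(0, 255, (120, 160))
        feats = extract_features(lbp_image(frame), tessellate(frame, 12, 16))
        assert np.all(feats >= 0)
        assert np.allclose(feats.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_per_tile_histograms(self, rng):
        frame = rng.integers(0, 255, (36, 48))
        grid = tessellate(frame, 12, 16)
        lbp = lbp_image(frame)
        feats = extract_features(lbp, grid)
        for idx in range(grid.n_tiles):
            sl = grid.tile_slices(idx)
            assert np.allclose(feats[idx], lbp_histogram(lbp[sl]))

    def test_two_textures_separate(self, rng):
        frame = two_texture_frame(rng)
        grid = tessellate(frame, 12, 16)
        feats = extract_features(lbp_image(frame), grid)
        labels = (np.arange(grid.n_tiles) % grid.n_cols) >= grid.n_cols // 2
        mu0, mu1 = feats[~labels].mean(axis=0), feats[labels].mean(axis=0)
        between = np.linalg.norm(mu0 - mu1)
        within = max(
            np.linalg.norm(feats[~labels] - mu0, axis=1).mean(),
            np.linalg.norm(feats[labels] - mu1, axis=1).mean(),
        )
        assert between > within

    def test_inconsistent_grid(self):
        grid = tessellate(np.zeros((24, 32)), 12, 16)
        with pytest.raises(ValidationError):
            extract_features(np.zeros((12, 16)), grid)


def gaussian_blob_features(rng, n=2000):
    centers = np.zeros((2, 9))
    centers[0, 0] = 5.0
    centers[1, 8] = 5.0
    labels = rng.integers(0, 2, n)
    feats = centers[labels] + 0.1 * rng.standard_normal((n, 9))
    return feats, labels


class TestFitTextureClassifier:
    def test_two_blobs_recovered(self, rng):
        feats, truth = gaussian_blob_features(rng)
        clf = fit_texture_classifier(feats, seed=0)
        pred = clf.predict(feats)
        agree = (pred == truth).mean()
        assert max(agree, 1 - agree) == 1.0  # Rand index 1 up to label swap

    def test_single_blob_no_crash(self, rng):
        feats = 0.05 * rng.standard_normal((500, 9))
        clf = fit_texture_classifier(feats, seed=1)
        assert set(np.unique(clf.predict(feats))) <= {0, 1}

    def test_deterministic_given_seed(self, rng):
        feats, _ = gaussian_blob_features(rng)
        a = fit_texture_classifier(feats, seed=3)
        b = fit_texture_classifier(feats, seed=3)
        assert np.array_equal(a.gmm.means_, b.gmm.means_)
        assert np.array_equal(a.gmm.weights_, b.gmm.weights_)
        assert a.label_map == b.label_map

    def test_degenerate_features_rejected(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_texture_classifier(np.tile(np.eye(9)[8], (100, 1)))

    def test_too_few_tiles(self, rng):
        with pytest.raises(ValidationError):
            fit_texture_classifier(rng.random((5, 9)), n_pca=5)

    def test_labeling_override(self, rng):
        feats, _ = gaussian_blob_features(rng)
        a = fit_texture_classifier(feats, seed=0, labeling="component0_is_cell")
        b = fit_texture_classifier(feats, seed=0, labeling="component1_is_cell")
        assert np.array_equal(a.predict(feats), 1 - b.predict(feats))

    def test_unknown_labeling_mode(self, rng):
        feats, _ = gaussian_blob_features(rng)
        with pytest.raises(ValidationError):
            fit_texture_classifier(feats, labeling="nope")


class TestBinarizeFrame:
    def test_two_texture_ground_truth(self, rng):
        frame = two_texture_frame(rng)
        grid = tessellate(frame, 12, 16)
        feats = extract_features(lbp_image(frame), grid)
        clf = fit_texture_classifier(feats, seed=0, labeling="auto")
        mask = binarize_frame(frame, clf, grid)
        tile_labels = mask.mask[:: grid.tile_height, :: grid.tile_width]
        truth = np.zeros_like(tile_labels)
        truth[:, grid.n_cols // 2 :] = True  # salt-and-pepper half = cell-like
        agree = (tile_labels == truth).mean()
        assert max(agree, 1 - agree) >= 0.95

    def test_constant_frame_uniform_label(self, rng):
        feats, _ = gaussian_blob_features(rng)
        clf = fit_texture_classifier(feats, seed=0)
        frame = np.full((24, 32), 7)
        mask = binarize_frame(frame, clf, tessellate(frame, 12, 16))
        assert len(np.unique(mask.mask)) == 1

    def test_mask_covers_grid_extent(self, rng):
        frame = rng.integers(0, 255, (25, 33))
        grid = tessellate(frame, 12, 16)
        feats, _ = gaussian_blob_features(rng)
        clf = fit_texture_classifier(feats, seed=0)
        mask = binarize_frame(frame, clf, grid)
        assert mask.mask.shape == grid.covered_shape

    def test_tiles_share_one_label(self, rng):
        frame = two_texture_frame(rng)
        grid = tessellate(frame, 12, 16)
        feats = extract_features(lbp_image(frame), grid)
        clf = fit_texture_classifier(feats, seed=0)
        mask = binarize_frame(frame, clf, grid).mask
        tiles = mask.reshape(grid.n_rows, grid.tile_height, grid.n_cols,
                             grid.tile_width)
        per_tile = tiles.transpose(0, 2, 1, 3).reshape(grid.n_tiles, -1)
        assert np.all(per_tile.min(axis=1) == per_tile.max(axis=1))

    def test_pure_function(self, rng):
        frame = two_texture_frame(rng)
        grid = tessellate(frame, 12, 16)
        feats = extract_features(lbp_image(frame), grid)
        clf = fit_texture_classifier(feats, seed=0)
        m1 = binarize_frame(frame, clf, grid).mask
        m2 = binarize_frame(frame, clf, grid).mask
        assert np.array_equal(m1, m2)

    def test_unfitted_classifier(self):
        from woundtrack.texture_segmentation import TextureClassifier

        frame = np.zeros((24, 32))
        with pytest.raises(ValidationError, match="not fitted"):
            binarize_frame(frame, TextureClassifier(), tessellate(frame, 12, 16))


@pytest.mark.parametrize("seed", range(10))
def test_segmentation_accuracy_across_seeds(seed):
    """PCA+GMM tile accuracy >= 0.95 on well-separated two-texture frames."""
    rng = np.random.default_rng(seed)
    frame = two_texture_frame(rng)
    grid = tessellate(frame, 12, 16)
    feats = extract_features(lbp_image(frame), grid)
    clf = fit_texture_classifier(feats, seed=seed)
    pred = clf.predict(feats)
    truth = ((np.arange(grid.n_tiles) % grid.n_cols) >= grid.n_cols // 2).astype(int)
    agree = (pred == truth).mean()
    assert max(agree, 1 - agree) >= 0.95
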