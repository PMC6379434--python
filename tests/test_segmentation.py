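"""Denoising, features, bisecting k-means, labeling and region spectra."""

import numpy as np
import pytest

from msi3d.core import (
    GridMetadata,
    IonImage,
    MassSpectrum,
    MsiDataset,
    MzInterval,
    PixelCoordinate,
)
from msi3d.segmentation import (
    BACKGROUND,
    GREY,
    TUMOR,
    WHITE,
    FeatureMatrix,
    bisecting_kmeans,
    build_features,
    denoise_image,
    label_regions,
    masks_to_rle,
    mean_spectrum,
)


class TestDenoise:
    def test_constant_unchanged(self):
        img = IonImage(np.full((6, 6), 4.0))
        np.testing.assert_array_equal(denoise_image(img, 1).values, img.values)

    def test_hot_pixel_replaced_by_neighborhood(self):
        v = np.full((5, 5), 2.0)
        v[2, 2] = 200.0
        out = denoise_image(IonImage(v), 1)
        assert out.values[2, 2] == 2.0

    def test_step_edge_preserved(self):
        v = np.zeros((6, 8))
        v[:, 4:] = 10.0
        out = denoise_image(IonImage(v), 1)
        np.testing.assert_array_equal(out.values, v)

    def test_missing_pixels_stay_missing(self):
        v = np.ones((4, 4))
        v[1, 2] = np.nan
        out = denoise_image(IonImage(v), 1)
        assert np.isnan(out.values[1, 2])
        assert np.isfinite(out.values).sum() == 15

    def test_radius_zero_is_identity(self):
        v = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(denoise_image(IonImage(v), 0).values, v)


def _toy_dataset(values_3x3, mz=500.0, grid=None):
    """3x3 section with one centroid per pixel carrying the given value."""
    grid = grid or GridMetadata()
    spectra = {}
    for y in range(3):
        for x in range(3):
            spectra[PixelCoordinate(x, y)] = MassSpectrum(
                [mz], [float(values_3x3[y][x])]
            )
    return MsiDataset(spectra=spectra, grid=grid)


class TestBuildFeatures:
    IV = [MzInterval(500.0, 0.5)]

    def test_row_count_equals_pixel_count(self):
        ds = _toy_dataset(np.ones((3, 3)))
        fm = build_features([ds], self.IV, radius=0)
        assert fm.values.shape == (9, 1)

    def test_radius_zero_equals_raw_binning(self):
        vals = np.arange(9.0).reshape(3, 3)
        fm = build_features([_toy_dataset(vals)], self.IV, radius=0)
        by_coord = {c: fm.values[i, 0] for i, (_, c) in enumerate(fm.pixels)}
        for y in range(3):
            for x in range(3):
                assert by_coord[PixelCoordinate(x, y)] == vals[y, x]

    def test_denoising_is_local_to_the_interval(self):
        """A hot pixel in one interval changes only that interval's column."""
        quiet = np.ones((3, 3))
        hot = quiet.copy()
        hot[1, 1] = 100.0
        ivs = [MzInterval(500.0, 0.5), MzInterval(600.0, 0.5)]
        spectra = {}
        for y in range(3):
            for x in range(3):
                spectra[PixelCoordinate(x, y)] = MassSpectrum(
                    [500.0, 600.0], [hot[y, x], 1.0]
                )
        ds = MsiDataset(spectra=spectra, grid=GridMetadata())
        fm0 = build_features([ds], ivs, radius=0)
        fm1 = build_features([ds], ivs, radius=1)
        # hot pixel smoothed away in column 0, column 1 identical
        np.testing.assert_array_equal(fm0.values[:, 1], fm1.values[:, 1])
        assert fm1.values[:, 0].max() == 1.0 < fm0.values[:, 0].max()

    def test_empty_interval_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_features([_toy_dataset(np.ones((3, 3)))], [], radius=0)


def _feature_matrix(values):
    values = np.asarray(values, dtype=float)
    pixels = [(0, PixelCoordinate(i, 0)) for i in range(values.shape[0])]
    ivs = [MzInterval(500.0 + j, 0.5) for j in range(values.shape[1])]
    return FeatureMatrix(values=values, pixels=pixels, intervals=ivs)


class TestBisectingKmeans:
    def test_two_orthogonal_templates_recovered_exactly(self):
        rng = np.random.default_rng(0)
        t1 = np.array([10.0, 1.0, 1.0, 10.0, 1.0, 1.0])
        t2 = np.array([1.0, 10.0, 1.0, 1.0, 10.0, 1.0])
        rows = np.vstack(
            [t1 * rng.lognormal(0, 0.05, 6) for _ in range(40)]
            + [t2 * rng.lognormal(0, 0.05, 6) for _ in range(40)]
        )
        tree = bisecting_kmeans(_feature_matrix(rows), max_leaves=2, min_leaf=5, seed=1)
        leaves = tree.leaves()
        assert len(leaves) == 2
        groups = [set(l.row_indices.tolist()) for l in leaves]
        assert {frozenset(g) for g in groups} == {
            frozenset(range(40)),
            frozenset(range(40, 80)),
        }

    def test_identical_rows_give_single_leaf(self):
        tree = bisecting_kmeans(
            _feature_matrix(np.tile([1.0, 2.0, 3.0], (30, 1))),
            max_leaves=4, min_leaf=2, seed=0,
        )
        assert len(tree.leaves()) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        rows = rng.lognormal(0, 0.5, (60, 8))
        t1 = bisecting_kmeans(_feature_matrix(rows), max_leaves=4, min_leaf=5, seed=9)
        t2 = bisecting_kmeans(_feature_matrix(rows), max_leaves=4, min_leaf=5, seed=9)
        np.testing.assert_array_equal(t1.leaf_assignment(), t2.leaf_assignment())

    def test_leaves_partition_pixels(self):
        rng = np.random.default_rng(2)
        rows = rng.lognormal(0, 0.5, (100, 6))
        tree = bisecting_kmeans(_feature_matrix(rows), max_leaves=5, min_leaf=5, seed=0)
        all_rows = np.concatenate([l.row_indices for l in tree.leaves()])
        assert sorted(all_rows.tolist()) == list(range(100))

    def test_scale_invariance_of_partition(self):
        """Correlation distance ignores a global positive rescaling."""
        rng = np.random.default_rng(3)
        rows = rng.lognormal(0, 0.5, (80, 6))
        a = bisecting_kmeans(_feature_matrix(rows), max_leaves=3, min_leaf=5, seed=4)
        b = bisecting_kmeans(_feature_matrix(rows * 37.5), max_leaves=3, min_leaf=5, seed=4)
        np.testing.assert_array_equal(a.leaf_assignment(), b.leaf_assignment())

    def test_single_row_warns_single_leaf(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            tree = bisecting_kmeans(_feature_matrix([[1.0, 2.0]]), seed=0)
        assert len(tree.leaves()) == 1


class TestLabelRegions:
    def _tree_with_leaves(self, leaf_pixel_lists):
        rows = []
        pixels = []
        for li, plist in enumerate(leaf_pixel_lists):
            for c in plist:
                pixels.append((0, c))
                rows.append([float(li), 1.0 - li])
        fm = FeatureMatrix(
            values=np.array(rows),
            pixels=pixels,
            intervals=[MzInterval(500.0, 0.5), MzInterval(600.0, 0.5)],
        )
        tree = bisecting_kmeans(fm, max_leaves=len(leaf_pixel_lists), min_leaf=1, seed=0)
        return tree

    def test_exact_masks_label_perfectly(self):
        g = [PixelCoordinate(x, 0) for x in range(5)]
        t = [PixelCoordinate(x, 1) for x in range(5)]
        tree = self._tree_with_leaves([g, t])
        label_regions(tree, {GREY: set(g), TUMOR: set(t)})
        labels = {frozenset(tuple(l.row_indices)) : l.label for l in tree.leaves()}
        assert set(labels.values()) == {GREY, TUMOR}

    def test_majority_overlap_wins(self):
        leaf = [PixelCoordinate(x, 0) for x in range(10)]
        tree = self._tree_with_leaves([leaf])
        tumor_mask = set(leaf[:8])
        grey_mask = set(leaf[8:]) | {PixelCoordinate(0, 5)}
        label_regions(tree, {TUMOR: tumor_mask, GREY: grey_mask})
        assert tree.leaves()[0].label == TUMOR

    def test_no_overlap_labels_background(self):
        leaf = [PixelCoordinate(x, 0) for x in range(4)]
        tree = self._tree_with_leaves([leaf])
        label_regions(tree, {TUMOR: {PixelCoordinate(9, 9)}})
        assert tree.leaves()[0].label == BACKGROUND

    def test_overlapping_masks_rejected(self):
        leaf = [PixelCoordinate(x, 0) for x in range(4)]
        tree = self._tree_with_leaves([leaf])
        shared = {PixelCoordinate(0, 0)}
        with pytest.raises(ValueError, match="overlap"):
            label_regions(tree, {TUMOR: shared, GREY: shared})


class TestMeanSpectrum:
    IV = [MzInterval(500.0, 0.5), MzInterval(600.0, 0.5)]

    def test_single_pixel_returns_its_values(self):
        ds = _toy_dataset(np.full((3, 3), 7.0))
        m = mean_spectrum([ds], {PixelCoordinate(0, 0)}, [MzInterval(500.0, 0.5)])
        assert m.intensity[0] == 7.0

    def test_two_pixel_mean(self):
        vals = np.zeros((3, 3))
        vals[0, 0], vals[0, 1] = 2.0, 4.0
        ds = _toy_dataset(vals)
        m = mean_spectrum(
            [ds], {PixelCoordinate(0, 0), PixelCoordinate(1, 0)},
            [MzInterval(500.0, 0.5)],
        )
        assert m.intensity[0] == pytest.approx(3.0)

    def test_matches_bruteforce_on_seven_pixels(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, (3, 3))
        ds = _toy_dataset(vals)
        region = [PixelCoordinate(x, y) for x in range(3) for y in range(3)][:7]
        m = mean_spectrum([ds], set(region), [MzInterval(500.0, 0.5)])
        brute = np.mean([vals[c.y, c.x] for c in region])
        assert m.intensity[0] == pytest.approx(brute)

    def test_unknown_pixel_fails(self):
        ds = _toy_dataset(np.ones((3, 3)))
        with pytest.raises(KeyError):
            mean_spectrum([ds], {PixelCoordinate(9, 9)}, self.IV)

    def test_empty_region_fails(self):
        ds = _toy_dataset(np.ones((3, 3)))
        with pytest.raises(ValueError, match="non-empty"):
            mean_spectrum([ds], set(), self.IV)


def test_masks_rle_round_trip():
    from msi3d.pipeline import load_masks_rle

    masks = {
        GREY: {PixelCoordinate(0, 0), PixelCoordinate(1, 0), PixelCoordinate(5, 2, 1)},
        TUMOR: {PixelCoordinate(3, 1)},
    }
    text = masks_to_rle(masks)
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "m.tsv"
        p.write_text(text)
        back = load_masks_rle(p)
    assert back == masks
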