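"""Feature stack, GLCM textures, thresholds, and the random-forest classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from treequity import canopy, synth


class TestIndices:
    def test_ndvi_zero_when_bands_equal(self):
        a = np.full((4, 4), 0.3)
        assert np.allclose(canopy.ndvi(a, a), 0.0)

    def test_ndvi_known_value(self):
        nir = np.array([[0.6]])
        red = np.array([[0.2]])
        assert canopy.ndvi(nir, red)[0, 0] == pytest.approx(0.5)

    def test_ndwi_boundary(self):
        g = np.array([[0.5]])
        nir = np.array([[0.0]])
        assert canopy.ndwi(g, nir)[0, 0] == pytest.approx(1.0)

    def test_zero_denominator_is_nodata(self):
        z = np.zeros((2, 2))
        assert np.isnan(canopy.ndvi(z, z)).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes differ"):
            canopy.ndvi(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_indices_bounded(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.01, 1, (2, 50, 50))
        for grid in (canopy.ndvi(a, b), canopy.gndvi(a, b), canopy.ndwi(a, b)):
            assert np.nanmax(np.abs(grid)) <= 1.0 + 1e-12


def _brute_window_entropy(q, levels, direction):
    """Independent oracle: enumerate symmetric co-occurrence pairs."""
    from collections import Counter

    pairs = Counter()
    h, w = q.shape
    di, dj = (0, 1) if direction == "h" else (1, 0)
    for i in range(h - di):
        for j in range(w - dj):
            a, b = q[i, j], q[i + di, j + dj]
            if a < 0 or b < 0:
                continue
            pairs[(a, b)] += 1
            pairs[(b, a)] += 1
    total = sum(pairs.values())
    if total == 0:
        return np.nan
    ps = np.array([c / total for c in pairs.values()])
    return float(-(ps * np.log(ps)).sum())


class TestGlcmEntropy:
    def test_constant_window_entropy_zero(self):
        grid = np.full((6, 6), 0.5)
        ent = canopy.glcm_entropy(grid, kernel=4, levels=8)
        assert np.allclose(ent, 0.0)

    def test_checkerboard_entropy_ln2(self):
        grid = np.indices((8, 8)).sum(axis=0) % 2
        ent = canopy.glcm_entropy(grid.astype(float), kernel=4, levels=2)
        assert np.allclose(ent, np.log(2), atol=1e-12)

    def test_entropy_bounded_by_ln_levels_squared(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(-1, 1, (12, 12))
        levels = 8
        ent = canopy.glcm_entropy(grid, kernel=4, levels=levels)
        assert np.nanmax(ent) <= np.log(levels**2) + 1e-9

    def test_matches_bruteforce_enumeration_per_window(self):
        """Fast path equals the direction-averaged brute-force oracle on
        random 4x4 windows cut from a random scene."""
        rng = np.random.default_rng(7)
        grid = rng.uniform(-0.5, 1.0, (10, 10))
        levels = 6
        ent = canopy.glcm_entropy(grid, kernel=4, levels=levels)
        lo, hi = grid.min(), grid.max()
        q = np.minimum(((grid - lo) / (hi - lo) * levels).astype(int), levels - 1)
        off = 1  # anchor offset documented in glcm_textures
        for i, j in [(3, 3), (5, 2), (2, 6), (6, 6), (0, 0), (9, 9)]:
            r0, r1 = max(0, i - off), min(10, i - off + 4)
            c0, c1 = max(0, j - off), min(10, j - off + 4)
            win = q[r0:r1, c0:c1]
            expected = np.mean(
                [_brute_window_entropy(win, levels, d) for d in ("h", "v")]
            )
            assert ent[i, j] == pytest.approx(expected, abs=1e-10)

    def test_matches_skimage_graycomatrix_single_direction(self):
        """Cross-check one window's horizontal symmetric GLCM entropy
        against scikit-image's co-occurrence matrix."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(11)
        levels = 5
        win = rng.integers(0, levels, (4, 4))
        codes = canopy._pair_codes_window(win.astype(np.int32), levels, "h")
        ours, _ = canopy._entropy_contrast_of_codes(codes, levels)
        glcm = graycomatrix(
            win.astype(np.uint8), [1], [0], levels=levels, symmetric=True, normed=True
        )[:, :, 0, 0]
        p = glcm[glcm > 0]
        assert ours == pytest.approx(float(-(p * np.log(p)).sum()), abs=1e-12)

    def test_kernel_larger_than_grid_raises(self):
        with pytest.raises(ValueError, match="kernel"):
            canopy.glcm_entropy(np.zeros((3, 3)), kernel=4)


class TestBinaryLayer:
    def test_infinite_threshold_gives_all_zero(self):
        ent = np.random.default_rng(0).uniform(0, 3, (5, 5))
        nd = np.full((5, 5), 0.9)
        thr = canopy.RegionThresholds(ndvi_min=0.0, entropy_min=np.inf)
        assert canopy.binary_texture_layer(ent, nd, thr).sum() == 0

    def test_conjunction_definition(self):
        thr = canopy.RegionThresholds(ndvi_min=0.3, entropy_min=1.0)
        ent = np.array([[2.0, 0.5]])
        nd = np.array([[0.6, 0.7]])
        out = canopy.binary_texture_layer(ent, nd, thr)
        assert out[0, 0] == 1  # textured and green
        assert out[0, 1] == 0  # grass-like: green but smooth

    def test_nodata_counts_as_zero(self):
        thr = canopy.RegionThresholds(ndvi_min=-1.0, entropy_min=0.0)
        out = canopy.binary_texture_layer(np.array([[np.nan]]), np.array([[np.nan]]), thr)
        assert out[0, 0] == 0


class TestChooseThresholds:
    def test_separable_features_reach_perfect_balanced_accuracy(self):
        pts = pd.DataFrame({"label": [1] * 20 + [0] * 20})
        ent = np.r_[np.full(20, 2.5), np.full(20, 0.5)]
        nd = np.r_[np.full(20, 0.8), np.full(20, 0.7)]
        thr = canopy.choose_thresholds(pts, entropy_at_points=ent, ndvi_at_points=nd)
        pred = (ent > thr.entropy_min) & (nd > thr.ndvi_min)
        assert (pred == pts["label"].to_numpy().astype(bool)).all()

    def test_random_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(5)
        n = 400
        ent = rng.uniform(0, 3, n)
        nd = rng.uniform(0, 1, n)
        pts = pd.DataFrame({"label": rng.integers(0, 2, n)})
        thr = canopy.choose_thresholds(pts, entropy_at_points=ent, ndvi_at_points=nd)
        pred = (ent > thr.entropy_min) & (nd > thr.ndvi_min)
        lab = pts["label"].to_numpy()
        bacc = 0.5 * (pred[lab == 1].mean() + (~pred[lab == 0]).mean())
        assert 0.45 <= bacc <= 0.62  # grid-search optimum over noise

    def test_tie_breaks_toward_higher_thresholds(self):
        # every threshold between the class values separates perfectly;
        # the tie must resolve to the high end of the candidate grid
        pts = pd.DataFrame({"label": [1, 1, 0, 0]})
        ent = np.array([3.0, 3.0, 0.1, 0.1])
        nd = np.array([0.9, 0.9, 0.1, 0.1])
        thr = canopy.choose_thresholds(pts, entropy_at_points=ent, ndvi_at_points=nd)
        pred = (ent > thr.entropy_min) & (nd > thr.ndvi_min)
        assert (pred == pts["label"].to_numpy().astype(bool)).all()
        assert thr.ndvi_min >= 0.7  # upper part of the feasible [0.1, 0.9) band
        assert thr.entropy_min >= 2.0

    def test_single_class_raises(self):
        pts = pd.DataFrame({"label": [1, 1, 1]})
        with pytest.raises(ValueError, match="both classes"):
            canopy.choose_thresholds(
                pts, entropy_at_points=np.ones(3), ndvi_at_points=np.ones(3)
            )


class TestAccuracy:
    def test_hand_computed_confusion(self):
        rep = canopy.accuracy_from_confusion([[40, 10], [5, 45]])
        assert rep.overall == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.70)

    def test_kappa_one_iff_diagonal(self):
        rep = canopy.accuracy_from_confusion([[50, 0], [0, 50]])
        assert rep.kappa == pytest.approx(1.0)

    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    def test_kappa_matches_bruteforce_formula(self, cells):
        cm = np.array(cells, dtype=float).reshape(2, 2)
        rep = canopy.accuracy_from_confusion(cm)
        n = cm.sum()
        po = (cm[0, 0] + cm[1, 1]) / n
        pe = (
            (cm[0, 0] + cm[0, 1]) * (cm[0, 0] + cm[1, 0])
            + (cm[1, 0] + cm[1, 1]) * (cm[0, 1] + cm[1, 1])
        ) / n**2
        assert rep.kappa == pytest.approx((po - pe) / (1 - pe) if pe < 1 else 1.0)
        assert rep.kappa <= rep.overall + 1e-12


class TestClassifier:
    def test_default_city_overall_accuracy(self, default_classification):
        assert default_classification["report"].overall >= 0.90

    def test_pixelwise_agreement_with_truth(self, default_city, default_classification):
        mask = default_classification["mask"]
        truth = default_city["truth"].canopy_mask
        assert (mask == truth).mean() >= 0.95

    def test_all_impervious_tile_classifies_as_no_tree(self, default_classification):
        cfg = synth.CityConfig(grid_extent_m=120, n_blocks=4, n_block_groups=4, n_tracts=1)
        cmap = np.full((60, 60), synth.CLASS_CODES["impervious"], dtype=np.uint8)
        img = synth.render_imagery(cmap, cfg, np.random.default_rng(4))
        stack = canopy.build_feature_stack(img, default_classification["thresholds"])
        mask = canopy.classify(stack, default_classification["model"])
        assert (mask == 0).mean() > 0.99

    def test_classification_deterministic(self, default_classification):
        m1 = canopy.classify(default_classification["stack"], default_classification["model"])
        m2 = canopy.classify(default_classification["stack"], default_classification["model"])
        assert np.array_equal(m1, m2)

    def test_degenerate_features_raise(self):
        from treequity.rasters import Raster

        data = np.zeros((10, 8, 8), dtype=np.float32)
        stack = canopy.FeatureStack(
            Raster(data, 2.0, band_names=list(canopy.FEATURE_BANDS))
        )
        pts = pd.DataFrame({"x": [1.0, 3.0], "y": [1.0, 3.0], "label": [0, 1]})
        with pytest.raises(ValueError, match="constant"):
            canopy.train_classifier(stack, pts, seed=0)

    def test_feature_stack_requires_ten_bands(self):
        from treequity.rasters import Raster

        with pytest.raises(ValueError, match="10 bands|exactly"):
            canopy.FeatureStack(Raster(np.zeros((9, 4, 4)), 2.0, band_names=["a"] * 9))
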