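"""Maximum-likelihood classification and crown dieback status tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

import treemort as tm
from treemort.mortality_classification import ThresholdCurve
from treemort.scenario import SyntheticScenario

from conftest import make_landscape


def _two_class_training(rng, n=50):
    a = rng.normal([10, 10, 10, 10], 1.0, size=(n, 4))
    b = rng.normal([100, 100, 100, 100], 1.0, size=(n, 4))
    pixels = np.vstack([a, b])
    labels = np.array(["live"] * n + ["dead"] * n)
    return pixels, labels


class TestTrainMlc:
    def test_identical_pixels_give_exact_mean_and_ridge_covariance(self):
        px = np.vstack([np.tile([5.0, 6.0, 7.0, 8.0], (6, 1)),
                        np.random.default_rng(0).normal(50, 1, (6, 4))])
        labels = np.array(["flat"] * 6 + ["other"] * 6)
        model = tm.train_mlc(px, labels)
        i = model.class_names.index("flat")
        np.testing.assert_allclose(model.means[i], [5.0, 6.0, 7.0, 8.0])
        assert "flat" in model.ridge_applied
        # ridge falls back to an absolute epsilon on a zero-trace covariance
        np.testing.assert_allclose(model.covs[i], np.eye(4) * 1e-6)

    def test_separable_classes_classify_training_set_perfectly(self):
        pixels, labels = _two_class_training(np.random.default_rng(1))
        model = tm.train_mlc(pixels, labels)
        pred = tm.classify_pixels(pixels, model)
        names = np.asarray(model.class_names)[pred]
        assert (names == labels).all()

    def test_moments_match_hand_computed_formulas(self):
        vecs = np.array([[1., 2., 3., 4.], [2., 3., 4., 5.], [0., 1., 2., 3.],
                         [4., 4., 4., 4.], [1., 0., 1., 0.], [3., 2., 1., 0.],
                         [5., 5., 5., 5.], [2., 2., 2., 2.], [0., 0., 0., 0.],
                         [1., 3., 5., 7.]])
        labels = np.array(["a"] * 5 + ["b"] * 5)
        model = tm.train_mlc(vecs, labels)
        for name in ("a", "b"):
            sel = vecs[labels == name]
            i = model.class_names.index(name)
            np.testing.assert_allclose(model.means[i], sel.sum(0) / 5)
            centered = sel - sel.mean(0)
            expected = centered.T @ centered / 4
            if name in model.ridge_applied:
                expected = expected + model.ridge_applied[name] * np.eye(4)
            np.testing.assert_allclose(model.covs[i], expected, atol=1e-12)

    def test_too_few_samples_per_class_raises(self):
        with pytest.raises(ValueError, match="need >= 5"):
            tm.train_mlc(np.ones((6, 4)), np.array(["a"] * 4 + ["b"] * 2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            tm.train_mlc(np.random.default_rng(0).normal(size=(10, 4)),
                         np.array(["a"] * 10))


class TestClassifyPixels:
    def _model(self, seed=2):
        pixels, labels = _two_class_training(np.random.default_rng(seed))
        return tm.train_mlc(pixels, labels)

    def test_pixel_at_class_mean_assigned_that_class(self):
        model = self._model()
        for i, name in enumerate(model.class_names):
            pred = tm.classify_pixels(model.means[[i]], model)
            assert model.class_names[pred[0]] == name

    def test_matches_direct_density_argmax_on_random_pixels(self):
        model = self._model()
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 110, size=(20, 4))
        pred = tm.classify_pixels(pts, model)
        dens = np.column_stack([
            multivariate_normal(model.means[i], model.covs[i]).logpdf(pts)
            + np.log(model.priors[i]) for i in range(len(model.class_names))])
        np.testing.assert_array_equal(pred, np.argmax(dens, axis=1))

    def test_argmax_tie_goes_to_lowest_class_index(self):
        # two identical class models: every pixel ties; lowest index wins
        px = np.vstack([np.random.default_rng(0).normal(0, 1, (6, 4)),
                        np.random.default_rng(0).normal(0, 1, (6, 4))])
        labels = np.array(["a"] * 6 + ["b"] * 6)
        model = tm.train_mlc(px, labels)
        pred = tm.classify_pixels(np.zeros((5, 4)), model)
        assert (pred == 0).all()

    def test_nan_bands_fall_back_to_background(self):
        pixels, labels = _two_class_training(np.random.default_rng(4))
        bg = np.random.default_rng(5).normal(60, 1, (10, 4))
        model = tm.train_mlc(np.vstack([pixels, bg]),
                             np.concatenate([labels, ["background"] * 10]))
        pts = np.array([[np.nan, 1, 1, 1], [10, 10, 10, 10]])
        pred = tm.classify_pixels(pts, model)
        assert model.class_names[pred[0]] == "background"

    def test_band_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="band count"):
            tm.classify_pixels(np.zeros((3, 3)), self._model())


class TestCrownDieback:
    def test_fraction_counts_dead_pixels(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[:2, :4] = 1  # 8-pixel crown
        dead = np.zeros((4, 4), dtype=np.uint8)
        dead[0, :3] = 1     # 3 of 8 dead
        frac = tm.crown_dead_fraction(labels, dead)
        assert frac.iloc[0]["dead_fraction"] == pytest.approx(0.375)

    @pytest.mark.parametrize("fill,expected", [(1, 1.0), (0, 0.0)])
    def test_uniform_crowns(self, fill, expected):
        labels = np.ones((3, 3), dtype=int)
        dead = np.full((3, 3), fill, dtype=np.uint8)
        frac = tm.crown_dead_fraction(labels, dead)
        assert frac.iloc[0]["dead_fraction"] == expected

    @pytest.mark.parametrize("fraction,expected", [
        (0.40, "dead"), (0.375, "live"), (0.0, "live")])
    def test_status_threshold_is_strict(self, fraction, expected):
        assert tm.classify_crown_status(fraction) == expected

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            tm.classify_crown_status(0.5, threshold=1.5)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 16 - 1))
    def test_flipping_live_pixel_to_dead_never_decreases_fraction(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=(8, 8))
        dead = rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
        if not (labels > 0).any():
            labels[0, 0] = 1
        base = tm.crown_dead_fraction(labels, dead).set_index("crown_id")
        live_px = np.argwhere(dead == 0)
        if len(live_px) == 0:
            return
        r, c = live_px[rng.integers(len(live_px))]
        dead2 = dead.copy()
        dead2[r, c] = 1
        after = tm.crown_dead_fraction(labels, dead2).set_index("crown_id")
        assert (after["dead_fraction"] >= base["dead_fraction"] - 1e-12).all()


class TestCalibrateThreshold:
    def test_separated_fractions_select_smallest_gap_threshold(self):
        frac = np.array([0.05, 0.10, 0.15, 0.60, 0.75, 0.90])
        truth = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        curve = tm.calibrate_threshold(frac, truth)
        assert isinstance(curve, ThresholdCurve)
        assert curve.selected_accuracy == 1.0
        # accuracy-1 thresholds run from 0.15 to <0.60; smallest grid value wins
        assert curve.selected == pytest.approx(0.15)

    def test_recovers_generator_threshold_within_one_grid_step(self):
        rng = np.random.default_rng(8)
        frac = rng.uniform(0, 1, size=400)
        truth = frac + rng.normal(0, 0.02, size=400) > 0.375
        if truth.all() or not truth.any():  # safeguard against degenerate draw
            pytest.fail("degenerate truth draw")
        curve = tm.calibrate_threshold(frac, truth, grid_step=0.025)
        assert abs(curve.selected - 0.375) <= 0.025 + 1e-9

    def test_curve_matches_confusion_matrix_oracle_at_spot_thresholds(self):
        rng = np.random.default_rng(9)
        frac = rng.uniform(0, 1, size=100)
        truth = rng.random(100) < frac
        curve = tm.calibrate_threshold(frac, truth).curve
        for t in (0.0, 0.25, 0.375, 0.5, 0.9):
            pred = frac > t
            tp = (pred & truth).sum()
            tn = (~pred & ~truth).sum()
            fp = (pred & ~truth).sum()
            fn = (~pred & truth).sum()
            row = curve[np.isclose(curve["threshold"], t)].iloc[0]
            assert row["accuracy"] == pytest.approx((tp + tn) / 100)
            assert row["fpr"] == pytest.approx(fp / (~truth).sum())
            assert row["fnr"] == pytest.approx(fn / truth.sum())

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            tm.calibrate_threshold([0.1, 0.9], [True, True])


def test_end_to_end_crown_status_accuracy(small_landscape, small_chm):
    """Full scene pipeline: with well-separated spectra, crown live/dead
    status must agree with generator truth for >= 95% of crowns."""
    from treemort.scenario import IMAGE_CLASSES

    year = 2016
    img, truth_classes = tm.render_imagery(small_landscape, year)
    tops = tm.detect_treetops(small_chm)
    cmap = tm.segment_crowns(small_chm, tops)
    # training pixels sampled from the truth raster
    rng = np.random.default_rng(12)
    pix, lab = [], []
    flat = img.reshape(4, -1).T
    tflat = truth_classes.ravel()
    for ci, cname in enumerate(IMAGE_CLASSES):
        idx = np.nonzero(tflat == ci)[0]
        take = rng.choice(idx, size=min(len(idx), 200), replace=False)
        pix.append(flat[take])
        lab += [cname] * len(take)
    model = tm.train_mlc(np.vstack(pix), np.array(lab),
                         class_names=list(IMAGE_CLASSES))
    classes = tm.classify_pixels(img, model)
    dead_raster = tm.collapse_to_dead(classes, model.class_names)
    frac = tm.crown_dead_fraction(cmap.labels, dead_raster)
    status = tm.classify_crown_status(frac["dead_fraction"].to_numpy())

    # truth per crown: the generator tree owning the apex pixel
    _, owner = tm.render_chm(small_landscape, return_owner=True)
    trees = small_landscape.trees.set_index("tree_id")
    apex_owner = owner[cmap.crowns["apex_row"], cmap.crowns["apex_col"]]
    dy = trees.loc[apex_owner, "death_year"].to_numpy()
    truth_dead = np.isfinite(dy) & (dy <= year)
    assert (status == truth_dead).mean() >= 0.95
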