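"""Bouton ROI detection chain: patches, HOG, SVM, seeds, growing, merging."""

import numpy as np
import pytest
from scipy import ndimage

from boutonmap.roi import (RoiConfig, detect_rois, erode_mask, find_seed,
                           hog_features, make_training_patches, match_rois,
                           parcellate, region_grow, train_bouton_classifier)


class TestParcellate:
    def test_512_image_stride4_patch_count(self):
        # oracle: floor((512-8)/4)+1 = 127 per axis, verified by enumeration
        img = np.zeros((512, 512))
        ps = parcellate(img, 8, 4)
        n_axis = len(range(0, 512 - 8 + 1, 4))
        assert n_axis == 127
        assert len(ps.positions) == 127 * 127 == 16129

    def test_exact_tiling_when_stride_equals_patch(self):
        ps = parcellate(np.zeros((512, 512)), 8, 8)
        assert len(ps.positions) == 4096

    def test_single_patch_image(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        ps = parcellate(img, 8, 4)
        assert len(ps.positions) == 1
        np.testing.assert_array_equal(ps.patches[0], img)

    def test_patches_reconstruct_source_pixels(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((32, 32))
        ps = parcellate(img, 8, 4)
        for (r, c), patch in zip(ps.positions, ps.patches):
            np.testing.assert_array_equal(patch, img[r:r + 8, c:c + 8])

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            parcellate(np.zeros((6, 6)), 8, 4)


class TestHogFeatures:
    def test_constant_patch_gives_zero_vector(self):
        f = hog_features(np.full((8, 8), 3.7))
        assert f.shape == (36,)  # 2x2 cells x 9 orientation bins
        assert np.all(f == 0)

    def test_vertical_step_edge_energy_in_horizontal_gradient_bin(self):
        patch = np.zeros((8, 8))
        patch[:, 4:] = 1.0  # vertical edge -> gradient along x
        cfg = RoiConfig(smooth_sigma=0.0)
        f = hog_features(patch, cfg).reshape(2, 2, 9)
        # unsigned orientation bin 0 collects horizontal-gradient energy
        energy = f.sum(axis=(0, 1))
        assert energy[0] == pytest.approx(energy.sum())

    def test_feature_scale_invariance(self):
        rng = np.random.default_rng(1)
        patch = rng.random((8, 8))
        np.testing.assert_allclose(hog_features(patch), hog_features(10 * patch),
                                   atol=1e-12)


class TestClassifier:
    def test_separable_fixture_trains_to_perfect_accuracy(self):
        # bright-blob patches vs pure-noise patches, pre-smoothed as in the
        # detection chain: linearly separable in HOG space (verified by
        # exhaustive prediction over the training set)
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[0:8, 0:8]
        pos = []
        for _ in range(100):
            cy, cx = rng.uniform(3, 5, 2)
            pos.append(np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.2**2))
                       + 0.05 * rng.standard_normal((8, 8)))
        neg = [0.05 * rng.standard_normal((8, 8)) for _ in range(100)]
        patches = ndimage.gaussian_filter(np.array(pos + neg), (0, 0.8, 0.8))
        labels = np.array([1] * 100 + [0] * 100)
        clf = train_bouton_classifier(patches, labels, seed=0,
                                      config=RoiConfig(svm_c=10.0))
        assert np.array_equal(clf.predict(patches), labels.astype(bool))

    def test_conflicting_duplicates_bound_by_majority(self):
        rng = np.random.default_rng(2)
        patch = rng.random((8, 8))
        patches = np.stack([patch] * 10)
        labels = np.array([1] * 7 + [0] * 3)
        clf = train_bouton_classifier(patches, labels, seed=0)
        acc = (clf.predict(patches) == labels.astype(bool)).mean()
        assert acc <= 0.7 + 1e-9

    def test_training_is_seed_deterministic(self):
        patches, labels = make_training_patches(80, seed=3)
        probe, _ = make_training_patches(40, seed=4)
        a = train_bouton_classifier(patches, labels, seed=1).predict(probe)
        b = train_bouton_classifier(patches, labels, seed=1).predict(probe)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        patches, _ = make_training_patches(10, seed=0)
        with pytest.raises(ValueError):
            train_bouton_classifier(patches, np.ones(len(patches)), seed=0)


class TestFindSeed:
    def test_centered_blob_seed_at_center(self):
        yy, xx = np.mgrid[0:9, 0:9]
        patch = np.exp(-((yy - 4) ** 2 + (xx - 4) ** 2) / (2 * 1.5**2))
        assert find_seed(patch, radii=(1, 4)) == (4, 4)

    def test_seed_confined_to_detected_circle(self):
        # disc with a crisp edge (detected by the Hough transform) plus a
        # brighter single-pixel speck outside it
        yy, xx = np.mgrid[0:21, 0:21]
        disc = (((yy - 10) ** 2 + (xx - 10) ** 2) <= 16).astype(float)
        patch = disc.copy()
        patch[10, 10] = 1.3  # brightest pixel inside the disc
        patch[1, 19] = 2.0  # global max, far from the circle
        seed = find_seed(patch, radii=(3, 6))
        assert ((seed[0] - 10) ** 2 + (seed[1] - 10) ** 2) <= 36
        assert seed != (1, 19)

    def test_flat_patch_falls_back_to_first_argmax(self):
        assert find_seed(np.zeros((8, 8))) == (0, 0)


class TestRegionGrow:
    def test_uniform_patch_threshold_zero_fills_patch(self):
        mask = region_grow(np.ones((6, 6)), (2, 2), 0.0)
        assert mask.all()

    def test_threshold_above_one_keeps_only_seed(self):
        rng = np.random.default_rng(0)
        patch = rng.random((8, 8)) + np.eye(8)  # seed strictly brightest
        seed = np.unravel_index(patch.argmax(), patch.shape)
        mask = region_grow(patch, seed, 1.01)
        assert mask.sum() == 1 and mask[seed]

    def test_hard_disc_recovered_exactly(self):
        # oracle: flood fill over the binary disc itself
        yy, xx = np.mgrid[0:15, 0:15]
        disc = ((yy - 7) ** 2 + (xx - 7) ** 2) <= 9
        patch = disc.astype(float)
        mask = region_grow(patch, (7, 7), 0.5, background=0.0)
        lab, _ = ndimage.label(disc, structure=np.ones((3, 3)))
        oracle = lab == lab[7, 7]
        np.testing.assert_array_equal(mask, oracle)

    def test_seed_outside_patch_rejected(self):
        with pytest.raises(ValueError):
            region_grow(np.ones((4, 4)), (9, 0), 0.5)


class TestErodeMask:
    def test_3x3_square_erodes_to_center(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        out = erode_mask(mask, 3)
        assert out.sum() == 1 and out[2, 2]

    def test_empty_mask_stays_empty(self):
        assert not erode_mask(np.zeros((5, 5), bool), 2).any()

    def test_touching_discs_become_disjoint(self):
        # two radius-3 discs sharing the single pixel (5, 8); the 1-px
        # bridge cannot contain a 2x2 element, so erosion separates them
        yy, xx = np.mgrid[0:11, 0:17]
        mask = (((yy - 5) ** 2 + (xx - 5) ** 2) <= 9) \
            | (((yy - 5) ** 2 + (xx - 11) ** 2) <= 9)
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 1  # connected before erosion
        out = erode_mask(mask, 2)
        lab, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 2


class TestDetectRois:
    def test_blank_image_yields_empty_roiset(self, trained_classifier):
        with pytest.warns(UserWarning):
            rois = detect_rois(np.zeros((64, 64)), trained_classifier)
        assert rois.n_rois == 0

    def test_benchmark_precision_and_recall(self, trained_classifier,
                                            detection_benchmark):
        scene, image = detection_benchmark
        rois = detect_rois(image, trained_classifier)
        _, precision, recall = match_rois(rois, scene.centers_px, tolerance_px=2.0)
        assert precision >= 0.8
        assert recall >= 0.8

    def test_detection_invariant_to_global_gain(self, trained_classifier,
                                                detection_benchmark):
        _, image = detection_benchmark
        a = detect_rois(image, trained_classifier)
        b = detect_rois(2.0 * image, trained_classifier)
        assert a.n_rois == b.n_rois

    def test_detection_deterministic(self, trained_classifier, detection_benchmark):
        _, image = detection_benchmark
        a = detect_rois(image, trained_classifier)
        b = detect_rois(image, trained_classifier)
        assert a.n_rois == b.n_rois
        for ma, mb in zip(a.masks, b.masks):
            np.testing.assert_array_equal(ma, mb)

    def test_mask_invariants(self, trained_classifier, detection_benchmark):
        _, image = detection_benchmark
        rois = detect_rois(image, trained_classifier)
        h, w = image.shape
        cfg = trained_classifier.config
        for m in rois.masks:
            assert m.any()
            lab, n = ndimage.label(m, structure=np.ones((3, 3)))
            assert n == 1  # 8-connected
        cents = rois.centroids_px()
        assert np.all((cents[:, 0] >= 0) & (cents[:, 0] < h))
        assert np.all((cents[:, 1] >= 0) & (cents[:, 1] < w))
        # no surviving pair above the merge threshold
        for i in range(rois.n_rois):
            for j in range(i + 1, rois.n_rois):
                inter = np.logical_and(rois.masks[i], rois.masks[j]).sum()
                if inter:
                    union = np.logical_or(rois.masks[i], rois.masks[j]).sum()
                    assert inter / union <= cfg.merge_iou
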