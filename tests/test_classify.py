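import warnings

import numpy as np
import pytest

from hsbrain.classify import (ClassifierConfig, OneBandImage, ProbabilityMap,
                              knn_filter, pca_first_component,
                              predict_probabilities, train_classifier,
                              training_fraction_curve)
from hsbrain.constants import CLASS_CODES, NORMAL, TUMOR
from hsbrain.hsio import HyperCube
from hsbrain.labeling import TrainingDataset


def _toy_dataset(n_per_class=20, seed=0):
    """Two linearly separable classes in 3 bands."""
    rng = np.random.default_rng(seed)
    a = rng.normal([1.0, 0.2, 0.2], 0.05, size=(n_per_class, 3))
    b = rng.normal([0.2, 0.2, 1.0], 0.05, size=(n_per_class, 3))
    X = np.vstack([a, b])
    y = np.array([NORMAL] * n_per_class + [TUMOR] * n_per_class)
    return TrainingDataset(X, y, np.zeros(len(y)))


class TestTrainClassifier:
    def test_separable_classes_resubstitute_perfectly(self):
        ds = _toy_dataset()
        model = train_classifier(ds)
        pred = [CLASS_CODES[int(np.argmax(p))]
                for p in model.predict_proba(ds.spectra)]
        assert np.mean(np.asarray(pred) == ds.labels) == 1.0

    def test_single_class_is_error(self):
        ds = _toy_dataset()
        one = TrainingDataset(ds.spectra[:20], ds.labels[:20], ds.groups[:20])
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(one)

    def test_tiny_class_is_error(self):
        ds = _toy_dataset()
        sel = np.r_[0:20, 20:21]
        bad = TrainingDataset(ds.spectra[sel], ds.labels[sel], ds.groups[sel])
        with pytest.raises(ValueError, match="fewer than two"):
            train_classifier(bad)

    def test_row_order_permutation_invariance(self):
        ds = _toy_dataset()
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(ds))
        shuffled = TrainingDataset(ds.spectra[perm], ds.labels[perm],
                                   ds.groups[perm])
        cfg = ClassifierConfig(seed=3)
        p1 = train_classifier(ds, cfg).predict_proba(ds.spectra)
        p2 = train_classifier(shuffled, cfg).predict_proba(ds.spectra)
        np.testing.assert_array_equal(p1, p2)

    def test_phantom_holdout_accuracy(self, fast_campaign, fast_preprocess):
        """Pixel-wise SVM accuracy on a held-out phantom subject is >= 95%
        before any spatial filtering."""
        from hsbrain import calibrate, preprocess

        _, scene, model = fast_campaign
        pp = preprocess(calibrate(scene.raw, scene.refs).cube,
                        fast_preprocess)
        probs = predict_probabilities(model, pp)
        labeled = scene.truth.labels != 0
        acc = np.mean(probs.argmax_classes()[labeled]
                      == scene.truth.labels[labeled])
        assert acc >= 0.95


class TestPredictProbabilities:
    def test_rows_sum_to_one(self, fast_campaign, fast_preprocess):
        from hsbrain import calibrate, preprocess

        _, scene, model = fast_campaign
        pp = preprocess(calibrate(scene.raw, scene.refs).cube,
                        fast_preprocess)
        probs = predict_probabilities(model, pp)
        np.testing.assert_allclose(probs.probs.sum(axis=2), 1.0, atol=1e-6)

    def test_band_mismatch_is_error(self):
        ds = _toy_dataset()
        model = train_classifier(ds)
        cube = HyperCube(np.ones((2, 2, 5)), np.arange(5) + 400.0)
        with pytest.raises(ValueError, match="bands"):
            predict_probabilities(model, cube)

    def test_training_exemplar_gets_its_class(self):
        ds = _toy_dataset(n_per_class=40)
        model = train_classifier(ds)
        cube = HyperCube(ds.spectra[0][None, None, :], np.arange(3) + 400.0)
        probs = predict_probabilities(model, cube)
        assert probs.argmax_classes()[0, 0] == ds.labels[0]


class TestPcaFirstComponent:
    def test_rank_one_cube_explains_all_variance(self):
        v = np.array([1.0, 2.0, 3.0])
        scales = np.arange(1, 10, dtype=float).reshape(3, 3)
        cube = HyperCube(scales[:, :, None] * v, np.arange(3) + 400.0)
        img = pca_first_component(cube)
        assert img.explained_variance_ratio == pytest.approx(1.0)

    def test_matches_closed_form_two_band_eigensolution(self):
        """Projections agree with the eigen-decomposition of the 2x2
        covariance matrix computed independently."""
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [1.0, 2.0]])
        cube = HyperCube(X.reshape(2, 2, 2), np.array([500.0, 600.0]))
        img = pca_first_component(cube)
        cov = np.cov(X.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        expected = (X - X.mean(axis=0)) @ lead
        np.testing.assert_allclose(img.values.ravel(), expected, atol=1e-9)

    def test_equal_spectra_diagonal_projections(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        cube = HyperCube(X.reshape(3, 1, 2), np.array([500.0, 600.0]))
        img = pca_first_component(cube)
        np.testing.assert_allclose(np.sort(img.values.ravel()),
                                   [-np.sqrt(2), 0.0, np.sqrt(2)], atol=1e-12)

    def test_sign_convention_stable_under_duplication(self, tiny_cube):
        img1 = pca_first_component(tiny_cube)
        doubled = HyperCube(np.concatenate([tiny_cube.data, tiny_cube.data]),
                            tiny_cube.wavelengths)
        img2 = pca_first_component(doubled)
        np.testing.assert_allclose(img2.values[:4], img1.values, atol=1e-9)

    def test_constant_cube_is_error(self):
        cube = HyperCube(np.full((2, 2, 3), 5.0), np.arange(3) + 400.0)
        with pytest.raises(ValueError, match="constant"):
            pca_first_component(cube)


def _brute_force_knn_mean(probs, guide, K, lam):
    """Independent O(n^2) oracle: exhaustive neighbour search + mean."""
    rows, cols, n_cls = probs.shape
    g = guide.astype(float)
    lo, hi = g.min(), g.max()
    g = (g - lo) / (hi - lo) if hi > lo else np.zeros_like(g)
    scale = 1.0 / max(rows, cols)
    feats = []
    for r in range(rows):
        for c in range(cols):
            feats.append((lam * r * scale, lam * c * scale, g[r, c]))
    feats = np.array(feats)
    flat = probs.reshape(-1, n_cls)
    out = np.zeros_like(flat)
    for i in range(len(feats)):
        d = np.sum((feats - feats[i]) ** 2, axis=1)
        nn = np.argsort(d, kind="stable")[:K]
        out[i] = flat[nn].mean(axis=0)
    out /= out.sum(axis=1, keepdims=True)
    return out.reshape(probs.shape)


def _random_probmap(rows, cols, seed):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(4), size=rows * cols)
    return ProbabilityMap(p.reshape(rows, cols, 4))


class TestKnnFilter:
    def test_uniform_probabilities_invariant(self):
        probs = ProbabilityMap(np.full((4, 4, 4), 0.25))
        guide = OneBandImage(np.random.default_rng(0).uniform(size=(4, 4)))
        out = knn_filter(probs, guide, K=5)
        np.testing.assert_allclose(out.probs, 0.25)

    def test_k_one_is_identity(self):
        probs = _random_probmap(4, 4, 1)
        guide = OneBandImage(np.random.default_rng(2).uniform(size=(4, 4)))
        out = knn_filter(probs, guide, K=1)
        np.testing.assert_allclose(out.probs, probs.probs, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 1.0, 3.0])
    def test_matches_brute_force_on_3x3(self, lam):
        probs = _random_probmap(3, 3, 4)
        guide_vals = np.arange(9, dtype=float).reshape(3, 3) ** 1.3  # no ties
        out = knn_filter(probs, OneBandImage(guide_vals), K=3,
                         spatial_weight=lam)
        expected = _brute_force_knn_mean(probs.probs, guide_vals, 3, lam)
        np.testing.assert_allclose(out.probs, expected, atol=1e-9)

    def test_large_lambda_is_spatial_mean(self):
        """With a huge spatial weight the guide value is negligible and the
        filter averages the spatially nearest K pixels."""
        probs = _random_probmap(3, 3, 6)
        guide = np.random.default_rng(7).uniform(size=(3, 3))
        out = knn_filter(probs, OneBandImage(guide), K=9, spatial_weight=1e9)
        expected = probs.probs.reshape(-1, 4).mean(axis=0)
        expected /= expected.sum()
        np.testing.assert_allclose(out.probs,
                                   np.broadcast_to(expected, (3, 3, 4)),
                                   atol=1e-9)

    def test_normalization_conserved(self):
        probs = _random_probmap(5, 5, 8)
        guide = OneBandImage(np.random.default_rng(9).uniform(size=(5, 5)))
        out = knn_filter(probs, guide, K=7, spatial_weight=0.5)
        np.testing.assert_allclose(out.probs.sum(axis=2), 1.0, atol=1e-12)

    def test_k_exceeding_pixels_is_error(self):
        probs = _random_probmap(2, 2, 0)
        guide = OneBandImage(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            knn_filter(probs, guide, K=5)

    def test_filtering_does_not_hurt_phantom_accuracy(
            self, fast_spec, fast_preprocess):
        """Aggregated over 10 phantom seeds, filtered argmax accuracy is at
        least the unfiltered accuracy (spatial homogenization helps or is
        neutral)."""
        from hsbrain import calibrate, generate_dataset, preprocess, train_classifier

        raw_accs, filt_accs = [], []
        for seed in range(10):
            ds, (scene,) = generate_dataset(
                fast_spec, n_subjects=2, seed=100 + seed, max_per_class=120,
                preprocess_config=fast_preprocess)
            model = train_classifier(ds, ClassifierConfig(seed=seed))
            pp = preprocess(calibrate(scene.raw, scene.refs).cube,
                            fast_preprocess)
            probs = predict_probabilities(model, pp)
            filt = knn_filter(probs, pca_first_component(pp), K=20)
            labeled = scene.truth.labels != 0
            truth = scene.truth.labels[labeled]
            raw_accs.append(np.mean(probs.argmax_classes()[labeled] == truth))
            filt_accs.append(np.mean(filt.argmax_classes()[labeled] == truth))
        assert np.mean(filt_accs) >= np.mean(raw_accs) - 1e-12


class TestTrainingFractionCurve:
    def test_full_fraction_reduces_to_plain_cv(self):
        ds = _toy_dataset(n_per_class=30)
        curve = training_fraction_curve(ds, [1.0], folds=3, seed=0)
        assert curve[0][0] == 1.0
        assert curve[0][1] == pytest.approx(1.0)  # separable toy

    def test_two_folds_on_four_samples(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 1.0], [1.1, 1.0]])
        y = np.array([NORMAL, NORMAL, TUMOR, TUMOR])
        ds = TrainingDataset(X, y, np.zeros(4))
        curve = training_fraction_curve(ds, [1.0], folds=2, seed=0)
        assert len(curve) == 1

    def test_vanishing_class_skipped_with_warning(self):
        ds = _toy_dataset(n_per_class=10)
        with pytest.warns(UserWarning, match="skipped"):
            curve = training_fraction_curve(ds, [0.05], folds=5, seed=0)
        assert curve == []

    def test_deterministic_given_seed(self):
        ds = _toy_dataset(n_per_class=25, seed=3)
        c1 = training_fraction_curve(ds, [0.5, 1.0], folds=3, seed=11)
        c2 = training_fraction_curve(ds, [0.5, 1.0], folds=3, seed=11)
        assert c1 == c2
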