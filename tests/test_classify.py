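"""Stratified splits, the classifier interface and map-accuracy metrics."""

import numpy as np
import pytest

from ecasii import (
    ClassifierSpec,
    LabelMap,
    SpectralImage,
    accuracy,
    classify_pixels,
    split_train_test,
)


def five_class_labels(h=25, w=25):
    lab = (np.arange(h * w).reshape(h, w) % 5) + 1
    return LabelMap(lab)


class TestSplit:
    def test_per_class_count(self):
        lab = five_class_labels()
        train, test = split_train_test(lab, per_class=25, seed=0)
        assert train.size == 125
        assert test.size == lab.labels.size - 125
        assert np.intersect1d(train, test).size == 0
        counts = np.bincount(lab.labels.ravel()[train])[1:]
        assert (counts == 25).all()

    def test_fraction(self):
        lab = LabelMap(np.repeat([1, 2], 100).reshape(10, 20))
        train, _ = split_train_test(lab, fraction=0.03, seed=0)
        assert train.size == 6  # 3 per 100-pixel class, 2 classes

    def test_total_budget_proportional(self):
        lab = five_class_labels(20, 20)
        train, test = split_train_test(lab, total=30, seed=0)
        assert train.size == 30
        assert test.size == 400 - 30

    def test_deterministic(self):
        lab = five_class_labels()
        a, _ = split_train_test(lab, per_class=10, seed=5)
        b, _ = split_train_test(lab, per_class=10, seed=5)
        assert np.array_equal(a, b)

    def test_small_class_takes_all_but_one(self):
        lab = LabelMap(np.array([[1, 1, 1, 1], [1, 1, 1, 2], [1, 1, 1, 2], [1, 1, 1, 2]]))
        with pytest.warns(UserWarning, match="all but one"):
            train, test = split_train_test(lab, per_class=5, seed=0)
        y = lab.labels.ravel()[train]
        assert (y == 2).sum() == 2  # class 2 has 3 pixels -> 2 in training

    def test_exactly_one_mode_required(self):
        with pytest.raises(ValueError):
            split_train_test(five_class_labels(), per_class=5, fraction=0.1)


class TestClassify:
    def test_centroid_separable_regions_perfect(self):
        lab = np.ones((10, 10), dtype=int)
        lab[:, 5:] = 2
        data = np.zeros((10, 10, 3))
        data[:, :5] = [1, 0, 0]
        data[:, 5:] = [0, 1, 0]
        truth = LabelMap(lab)
        img = SpectralImage(data)
        train, test = split_train_test(truth, per_class=5, seed=0)
        pred = classify_pixels(img, train, truth, ClassifierSpec(kind="centroid"))
        rep = accuracy(pred, truth, mask=test)
        assert rep.oa == 100.0

    def test_single_training_class_constant_map(self, rng):
        img = SpectralImage(rng.random((6, 6, 3)))
        truth = LabelMap(np.full((6, 6), 4))
        pred = classify_pixels(img, np.arange(5), truth, ClassifierSpec(kind="svm"))
        assert np.unique(pred.raw).tolist() == [4]

    @pytest.mark.parametrize("kind", ["svm", "centroid"])
    def test_interface_interchangeable(self, rng, kind):
        """Both classifiers fit the same call signature and label every pixel."""
        lab = np.ones((12, 12), dtype=int)
        lab[:, 6:] = 2
        truth = LabelMap(lab)
        data = np.where(lab[..., None] == 1, [0.9, 0.1, 0.1], [0.1, 0.9, 0.1])
        img = SpectralImage(data + 0.05 * rng.standard_normal((12, 12, 3)))
        train, test = split_train_test(truth, per_class=10, seed=0)
        pred = classify_pixels(img, train, truth, ClassifierSpec(kind=kind, seed=0))
        assert pred.shape == truth.shape
        assert accuracy(pred, truth, mask=test).oa > 90.0


class TestAccuracy:
    def test_perfect_prediction(self):
        truth = five_class_labels(10, 10)
        rep = accuracy(truth, truth)
        assert rep.oa == rep.aa == rep.kappa == 100.0

    def test_known_confusion_matrix(self):
        """Confusion [[50, 0], [10, 40]]: OA 90, AA 90, kappa 80."""
        t = np.concatenate([np.ones(50), np.full(50, 2)]).astype(int)
        p = t.copy()
        p[50:60] = 1
        rep = accuracy(LabelMap(t.reshape(10, 10)), LabelMap(p.reshape(10, 10)))
        # accuracy(pred, truth): first arg is the prediction
        rep = accuracy(LabelMap(p.reshape(10, 10)), LabelMap(t.reshape(10, 10)))
        assert rep.oa == pytest.approx(90.0)
        assert rep.aa == pytest.approx(90.0)
        assert rep.kappa == pytest.approx(80.0)
        assert np.array_equal(rep.confusion, [[50, 0], [10, 40]])

    def test_constant_prediction_zero_kappa(self):
        t = np.concatenate([np.ones(50), np.full(50, 2)]).astype(int)
        pred = LabelMap(np.ones((10, 10), dtype=int))
        rep = accuracy(pred, LabelMap(t.reshape(10, 10)))
        assert rep.kappa == pytest.approx(0.0)
        assert rep.oa == pytest.approx(50.0)

    def test_kappa_never_exceeds_oa(self, rng):
        for _ in range(5):
            t = LabelMap(rng.integers(1, 4, size=(12, 12)))
            p = LabelMap(rng.integers(1, 4, size=(12, 12)))
            rep = accuracy(p, t)
            assert rep.kappa <= rep.oa + 1e-9

    def test_mask_restricts_evaluation(self):
        truth = five_class_labels(10, 10)
        pred = LabelMap(np.ones((10, 10), dtype=int))
        mask = np.flatnonzero(truth.labels.ravel() == 1)
        rep = accuracy(pred, truth, mask=mask)
        assert rep.oa == 100.0

    def test_empty_mask_rejected(self):
        truth = five_class_labels(10, 10)
        with pytest.raises(ValueError, match="empty"):
            accuracy(truth, truth, mask=np.array([], dtype=int))
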