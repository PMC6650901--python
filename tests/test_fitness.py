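"""Intra/inter-class cost components against naive oracle implementations."""

import warnings

import numpy as np
import pytest

from ecasii import (
    FitnessConfig,
    LabelMap,
    SpectralImage,
    derive_ground_truth,
    spectral_angle,
    total_cost,
)
from ecasii.fitness import (
    class_homogeneity,
    inter_error,
    local_intra_error,
    nonlocal_intra_error,
    _all_homogeneities,
)

# ---------------------------------------------------------------------------
# naive oracles (double loops; share the implementation's sample streams)
# ---------------------------------------------------------------------------

def neighbor_angle_oracle(img, y, x):
    h, w, _ = img.data.shape
    angles = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == dx == 0:
                continue
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                angles.append(spectral_angle(img.data[y, x], img.data[yy, xx]))
    return float(np.mean(angles))


def local_intra_oracle(img, gt):
    num = 0.0
    den = 0
    w = img.data.shape[1]
    for k in sorted(gt.interior):
        for p in gt.interior[k]:
            num += neighbor_angle_oracle(img, p // w, p % w)
            den += 1
    return num / den if den else 0.0


def homogeneity_oracle(img, gt, k):
    idx = gt.interior[k]
    if idx.size == 0:
        return 0.0
    w = img.data.shape[1]
    return float(np.mean([neighbor_angle_oracle(img, p // w, p % w) for p in idx]))


def nonlocal_oracle(img, gt, cfg, rng):
    """Consumes the same random stream as the implementation."""
    spectra = img.data.reshape(-1, img.bands)
    num = den = 0.0
    for k in sorted(gt.interior):
        idx = gt.interior[k]
        if idx.size < 1:
            continue
        pairs = rng.integers(0, idx.size, size=(cfg.V, 2))
        angs = [
            spectral_angle(spectra[idx[a]], spectra[idx[b]]) for a, b in pairs
        ]
        num += np.mean(angs) * idx.size
        den += idx.size
    return num / den if den else 0.0


def inter_oracle(img, gt, hk, cfg, rng):
    spectra = img.data.reshape(-1, img.bands)
    classes = sorted(gt.interior)
    outer_num = outer_den = 0.0
    for k in classes:
        inner_num = inner_den = 0.0
        for k2 in classes:
            if k2 == k:
                continue
            f1 = gt.shared_border.get((k, k2))
            f2 = gt.shared_border.get((k2, k))
            if f1 is None or f2 is None or not len(f1) or not len(f2):
                continue
            xs = f1[rng.integers(0, len(f1), size=cfg.U)]
            ys = f2[rng.integers(0, len(f2), size=cfg.U)]
            hits = [
                spectral_angle(spectra[a], spectra[b]) <= hk[k - 1] + hk[k2 - 1]
                for a, b in zip(xs, ys)
            ]
            inner_num += np.mean(hits) * gt.region_size[k2]
            inner_den += gt.region_size[k2]
        if inner_den:
            outer_num += inner_num / inner_den * gt.region_size[k]
            outer_den += gt.region_size[k]
    return outer_num / outer_den if outer_den else 0.0


def three_class_case(rng, h=12, w=12, bands=3):
    lab = np.ones((h, w), dtype=int)
    lab[:, w // 3 : 2 * w // 3] = 2
    lab[:, 2 * w // 3 :] = 3
    img = SpectralImage(rng.random((h, w, bands)))
    return img, derive_ground_truth(LabelMap(lab))


# ---------------------------------------------------------------------------
# ground-truth derivation
# ---------------------------------------------------------------------------

class TestGroundTruth:
    def test_halfplane_borders_and_shared_sets(self, halfplane_labels):
        gt = derive_ground_truth(halfplane_labels)
        border_cols = {p % 10 for p in np.concatenate([gt.border[1], gt.border[2]])}
        assert border_cols == {4, 5}
        assert gt.shared_border[(1, 2)].size == 10
        assert gt.shared_border[(2, 1)].size == 10
        assert gt.region_size == {1: 50, 2: 50}

    def test_single_class_all_interior(self):
        gt = derive_ground_truth(LabelMap(np.ones((5, 5), dtype=int)))
        assert gt.interior[1].size == 25
        assert gt.border[1].size == 0
        assert gt.shared_border == {}

    def test_checkerboard_all_border(self):
        lab = (np.indices((8, 8)).sum(axis=0) % 2) + 1
        gt = derive_ground_truth(LabelMap(lab))
        assert all(gt.interior[k].size == 0 for k in (1, 2))
        assert gt.border[1].size + gt.border[2].size == 64

    def test_partition_is_disjoint_and_complete(self, small_scene):
        gt = derive_ground_truth(small_scene.labels)
        pieces = [gt.interior[k] for k in gt.interior] + [gt.border[k] for k in gt.border]
        allpix = np.concatenate(pieces)
        assert np.array_equal(np.sort(allpix), np.arange(small_scene.labels.labels.size))


# ---------------------------------------------------------------------------
# components vs oracles
# ---------------------------------------------------------------------------

class TestComponents:
    def test_piecewise_constant_scores_zero(self, halfplane_labels):
        data = np.zeros((10, 10, 3))
        data[:, :5] = [1, 0, 0]
        data[:, 5:] = [0, 1, 0]
        img = SpectralImage(data)
        gt = derive_ground_truth(halfplane_labels)
        assert local_intra_error(img, gt) == 0.0
        assert nonlocal_intra_error(img, gt, FitnessConfig(seed=0)) == 0.0
        rep = total_cost(img, gt, FitnessConfig(seed=0))
        assert rep.e == 0.0  # distinct constant regions: ideal segmentation

    def test_local_intra_matches_oracle(self, rng):
        img, gt = three_class_case(rng)
        assert local_intra_error(img, gt) == pytest.approx(
            local_intra_oracle(img, gt), abs=1e-12
        )

    def test_homogeneity_matches_oracle(self, rng):
        img, gt = three_class_case(rng)
        for k in (1, 2, 3):
            assert class_homogeneity(img, gt, k) == pytest.approx(
                homogeneity_oracle(img, gt, k), abs=1e-12
            )

    def test_nonlocal_matches_oracle_shared_stream(self, rng):
        img, gt = three_class_case(rng)
        cfg = FitnessConfig(V=50, U=50, seed=99)
        ours = nonlocal_intra_error(img, gt, cfg)
        oracle = nonlocal_oracle(img, gt, cfg, np.random.default_rng(99))
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_nonlocal_two_spectra_expectation(self):
        """Interior pixels split between two spectra at angle a: the expected
        pair angle is a/2 (half the pairs mix the spectra)."""
        h = w = 40
        lab = LabelMap(np.ones((h, w), dtype=int))
        data = np.zeros((h, w, 2))
        data[:, : w // 2] = [1.0, 0.0]
        data[:, w // 2 :] = [0.0, 1.0]
        img = SpectralImage(data)
        gt = derive_ground_truth(lab)
        est = nonlocal_intra_error(img, gt, FitnessConfig(V=10000, seed=5))
        assert est == pytest.approx(0.5, abs=0.02)  # a = 1, E = a/2, MC error

    def test_inter_matches_oracle_shared_stream(self, rng):
        img, gt = three_class_case(rng)
        hk = _all_homogeneities(img, gt)
        cfg = FitnessConfig(V=50, U=50, seed=7)
        ours = inter_error(img, gt, hk, cfg)
        oracle = inter_oracle(img, gt, hk, cfg, np.random.default_rng(7))
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_constant_image_two_classes_scores_one(self, halfplane_labels):
        img = SpectralImage(np.full((10, 10, 4), 0.5))
        gt = derive_ground_truth(halfplane_labels)
        rep = total_cost(img, gt, FitnessConfig(seed=0))
        assert rep.e_inter == 1.0
        assert rep.e == 1.0

    def test_total_is_max_of_components(self, rng):
        img, gt = three_class_case(rng)
        rep = total_cost(img, gt, FitnessConfig(seed=3))
        assert rep.e_intra == max(rep.e_local_intra, rep.e_nonlocal_intra)
        assert rep.e == max(rep.e_intra, rep.e_inter)
        for v in (rep.e_local_intra, rep.e_nonlocal_intra, rep.e_inter, rep.e):
            assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

class TestInvariances:
    def test_scale_invariance(self, rng):
        img, gt = three_class_case(rng)
        scaled = SpectralImage(img.data * 7.3)
        a = total_cost(img, gt, FitnessConfig(seed=11))
        b = total_cost(scaled, gt, FitnessConfig(seed=11))
        assert a.e == pytest.approx(b.e, abs=1e-9)
        assert a.e_local_intra == pytest.approx(b.e_local_intra, abs=1e-9)

    def test_seeded_reproducibility(self, rng):
        img, gt = three_class_case(rng)
        a = total_cost(img, gt, FitnessConfig(seed=21))
        b = total_cost(img, gt, FitnessConfig(seed=21))
        assert a.e == b.e
        assert a.e_nonlocal_intra == b.e_nonlocal_intra

    def test_single_class_inter_is_zero(self, rng):
        img = SpectralImage(rng.random((8, 8, 3)))
        gt = derive_ground_truth(LabelMap(np.ones((8, 8), dtype=int)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = total_cost(img, gt, FitnessConfig(seed=0))
        assert rep.e_inter == 0.0
        assert rep.e == rep.e_intra
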