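"""The cellular-automaton engine against brute-force oracles and geometry."""

import numpy as np
import pytest

from ecasii import RuleSet, SpectralImage, spectral_angle
from ecasii.masks import WINDOW_SIZES, mask_bank
from ecasii.mgca import (
    GradientFeature,
    UpdateConfig,
    extract_gradient_fields,
    extract_gradients,
    match_rule,
    run_mgca,
    update_cell,
    update_image,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def gradient_oracle(img: SpectralImage, cell):
    """Naive double-loop evaluation of the mask-weighted angle sums."""
    y, x = cell
    data = img.data
    padded = np.pad(data, ((3, 3), (3, 3), (0, 0)), mode="symmetric")
    center = data[y, x]
    gx = np.zeros(3)
    gy = np.zeros(3)
    for si, ns in enumerate(WINDOW_SIZES):
        r = ns // 2
        mx, my = mask_bank()[ns]
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                a = spectral_angle(center, padded[3 + y + dy, 3 + x + dx])
                gx[si] += a * mx[dy + r, dx + r]
                gy[si] += a * my[dy + r, dx + r]
    return gx, gy


def match_oracle(feat, rules, n_angles=4096):
    """Exhaustive rotation grid x reflection scan of the matching distance."""
    vx, vy = rules.condition_vectors()
    best = (np.inf, -1, 0.0, False)
    for k in range(rules.n_rules):
        for refl in (False, True):
            vyk = -vy[k] if refl else vy[k]
            for psi in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
                c, s = np.cos(psi), np.sin(psi)
                rx = c * vx[k] - s * vyk
                ry = s * vx[k] + c * vyk
                d = np.sum(np.hypot(feat.gx - rx, feat.gy - ry))
                if d < best[0]:
                    best = (d, k, psi, refl)
    return best


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

class TestGradients:
    def test_uniform_image_zero_moduli_zero_angles(self):
        img = SpectralImage(np.full((8, 8, 4), 0.3))
        feat = extract_gradients(img, (4, 4))
        assert np.allclose(feat.moduli, 0.0, atol=1e-12)
        assert np.array_equal(feat.angles, np.zeros(3))

    def test_vertical_step_edge(self):
        """Cell just right of an orthogonal step edge: the three left window
        cells sit at angle 1, the rest at 0, so GX3 = -1 and phi3 = pi."""
        img = np.zeros((9, 9, 2))
        img[:, :4] = [1.0, 0.0]
        img[:, 4:] = [0.0, 1.0]
        feat = extract_gradients(SpectralImage(img), (4, 4))
        assert feat.gx[0] == pytest.approx(-1.0, abs=1e-12)
        assert feat.gy[0] == pytest.approx(0.0, abs=1e-12)
        assert feat.moduli[0] == pytest.approx(1.0, abs=1e-12)
        assert feat.angles[0] == pytest.approx(np.pi, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        img = SpectralImage(rng.random((16, 16, 5)))
        gx, gy = extract_gradient_fields(img)
        for cell in [(0, 0), (1, 15), (7, 8), (15, 0), (3, 3)]:
            ox, oy = gradient_oracle(img, cell)
            assert np.allclose(gx[cell], ox, atol=1e-12)
            assert np.allclose(gy[cell], oy, atol=1e-12)
            feat = extract_gradients(img, cell)
            assert np.allclose(feat.gx, ox, atol=1e-12)


# ---------------------------------------------------------------------------
# rule matching
# ---------------------------------------------------------------------------

class TestMatching:
    def test_exact_match(self, rng):
        rules = RuleSet.random(6, rng)
        vx, vy = rules.condition_vectors()
        idx, phi, refl, d = match_rule(GradientFeature(vx[3].copy(), vy[3].copy()), rules)
        assert (idx, refl) == (3, False)
        assert d == pytest.approx(0.0, abs=1e-7)
        assert phi == pytest.approx(0.0, abs=1e-7) or phi == pytest.approx(2 * np.pi, abs=1e-7)

    @pytest.mark.parametrize("psi", [0.5, 2.0, 4.5])
    def test_rotation_recovered(self, rng, psi):
        rules = RuleSet.random(6, rng)
        vx, vy = rules.condition_vectors()
        c, s = np.cos(psi), np.sin(psi)
        feat = GradientFeature(c * vx[2] - s * vy[2], s * vx[2] + c * vy[2])
        idx, phi, refl, d = match_rule(feat, rules)
        assert idx == 2 and not refl
        assert d == pytest.approx(0.0, abs=1e-7)
        assert phi == pytest.approx(psi, abs=1e-7)

    def test_reflection_recovered(self, rng):
        rules = RuleSet.random(6, rng)
        vx, vy = rules.condition_vectors()
        idx, phi, refl, d = match_rule(GradientFeature(vx[1].copy(), -vy[1]), rules)
        assert idx == 1 and refl
        assert d == pytest.approx(0.0, abs=1e-7)

    def test_distance_invariant_under_common_rotation(self, rng):
        rules = RuleSet.random(10, rng)
        g = GradientFeature(rng.normal(size=3), rng.normal(size=3))
        _, _, _, d0 = match_rule(g, rules)
        psi = 1.7
        c, s = np.cos(psi), np.sin(psi)
        g2 = GradientFeature(c * g.gx - s * g.gy, s * g.gx + c * g.gy)
        _, _, _, d1 = match_rule(g2, rules)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_against_grid_oracle(self, rng):
        """Closed-form candidate rotations agree with a 4096-step grid scan."""
        rules = RuleSet.random(30, rng)
        grid_tol = 2 * np.pi / 4096 * 10  # distance varies Lipschitz-ly in psi
        for _ in range(5):
            feat = GradientFeature(0.5 * rng.normal(size=3), 0.5 * rng.normal(size=3))
            idx, phi, refl, d = match_rule(feat, rules)
            d_o, k_o, psi_o, refl_o = match_oracle(feat, rules)
            assert abs(d - d_o) < grid_tol


# ---------------------------------------------------------------------------
# state update
# ---------------------------------------------------------------------------

class TestUpdate:
    def test_uniform_fixed_point(self):
        img = SpectralImage(np.full((6, 6, 3), 0.7))
        out = update_cell(img, (3, 3), 0.8, 1.1)
        assert np.allclose(out, img.data[3, 3], atol=1e-12)

    def test_axis_landing_weights(self):
        """Attraction point on the east neighbor q: with f_th = 2 the weights
        are q: 2/7, q's three other axis neighbors: 1/7 each, self: 2/7."""
        data = np.zeros((5, 5, 1))
        spectra = {}
        for i, (yy, xx) in enumerate([(2, 2), (2, 3), (2, 4), (1, 3), (3, 3)]):
            data[yy, xx, 0] = float(i + 1)
            spectra[(yy, xx)] = float(i + 1)
        img = SpectralImage(data)
        out = update_cell(img, (2, 2), 0.0, 0.0, UpdateConfig(f_th=2.0))
        expected = (
            2 / 7 * spectra[(2, 3)]
            + 1 / 7 * (spectra[(2, 4)] + spectra[(1, 3)] + spectra[(3, 3)])
            + 2 / 7 * spectra[(2, 2)]
        )
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_weights_form_convex_combination(self, rng):
        img = SpectralImage(rng.random((7, 7, 4)))
        direction = rng.uniform(0, 2 * np.pi, size=(7, 7))
        out = update_image(img.data, direction, f_th=2.0)
        assert out.min() >= img.data.min() - 1e-12
        assert out.max() <= img.data.max() + 1e-12

    def test_batch_matches_per_cell(self, rng):
        img = SpectralImage(rng.random((6, 6, 3)))
        direction = rng.uniform(0, 2 * np.pi, size=(6, 6))
        batch = update_image(img.data, direction, f_th=2.0)
        for cell in [(0, 0), (0, 5), (3, 2), (5, 5)]:
            single = update_cell(img, cell, direction[cell], 0.0, UpdateConfig(f_th=2.0))
            assert np.allclose(batch[cell], single, atol=1e-12)


# ---------------------------------------------------------------------------
# iteration loop
# ---------------------------------------------------------------------------

class TestRunMGCA:
    def test_k0_identity(self, random_image, rng):
        rules = RuleSet.random(5, rng)
        out = run_mgca(random_image, rules, UpdateConfig(iterations=0))
        assert np.array_equal(out.data, random_image.data)

    def test_uniform_fixed_point_any_rules(self, rng):
        img = SpectralImage(np.full((10, 10, 6), 0.42))
        for _ in range(3):
            rules = RuleSet.random(8, rng)
            out = run_mgca(img, rules, UpdateConfig(iterations=4))
            assert np.allclose(out.data, img.data, atol=1e-12)

    @pytest.mark.parametrize("bands", [3, 64])
    def test_shape_preserved_values_bounded(self, rng, bands):
        img = SpectralImage(rng.random((12, 12, bands)))
        rules = RuleSet.random(6, rng)
        out = run_mgca(img, rules, UpdateConfig(iterations=3))
        assert out.shape == img.shape
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_deterministic(self, random_image, rng):
        rules = RuleSet.random(6, rng)
        a = run_mgca(random_image, rules, UpdateConfig(iterations=3))
        b = run_mgca(random_image, rules, UpdateConfig(iterations=3))
        assert np.array_equal(a.data, b.data)
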