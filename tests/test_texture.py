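import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from soilhsi import GLCMConfig, glcm, glcm_stats, quantize, texture_features
from soilhsi.synthetic_data import correlated_field
from soilhsi.texture import DIRECTIONS_DEG, _OFFSETS


class TestQuantize:
    def test_constant_image_maps_to_zero(self):
        np.testing.assert_array_equal(quantize(np.full((3, 3), 4.2), 64), 0)

    def test_binary_image_two_levels(self):
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(quantize(img, 2), img.astype(int))

    def test_hand_example_four_levels(self):
        # min-max to [0,1], floor(v*L) clipped to L-1
        np.testing.assert_array_equal(
            quantize(np.array([[0.0, 0.5, 1.0]]), 4), [[0, 2, 3]]
        )


CHECKERBOARD = np.array([[0, 1], [1, 0]])


class TestGlcm:
    def test_checkerboard_horizontal(self):
        P = glcm(CHECKERBOARD, 0, levels=2)
        np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_image_single_diagonal_cell(self):
        P = glcm(np.full((4, 4), 3, dtype=int), 0, levels=5)
        expected = np.zeros((5, 5))
        expected[3, 3] = 1.0
        np.testing.assert_allclose(P, expected)

    def test_row_stripes_horizontal_diagonal_only(self):
        img = np.repeat(np.arange(4)[:, None], 5, axis=1)  # constant along rows
        P = glcm(img, 0, levels=4)
        np.testing.assert_allclose(P, np.diag(np.diag(P)))
        assert np.trace(P) == pytest.approx(1.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            glcm(np.array([[0], [1]]), 0, levels=2)

    @pytest.mark.parametrize("direction", DIRECTIONS_DEG)
    def test_matches_skimage_oracle(self, rng, direction):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, size=(12, 15))
        mine = glcm(img, direction, levels=8)
        # our diagonal offsets step up-row, skimage's step down-row; the
        # symmetric GLCM of offset o equals that of -o, i.e. the mirrored angle
        angle = np.deg2rad({0: 0, 45: 135, 90: 90, 135: 45}[direction])
        theirs = graycomatrix(
            img.astype(np.uint8), [1], [angle], levels=8, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(mine, theirs, atol=1e-12)

    @pytest.mark.parametrize("direction", DIRECTIONS_DEG)
    def test_symmetric_glcm_invariant_to_flip_along_offset(self, rng, direction):
        img = rng.integers(0, 6, size=(9, 9))
        dr, dc = _OFFSETS[direction]
        flipped = img[::-1] if dc == 0 else img[:, ::-1] if dr == 0 else img[::-1, ::-1]
        np.testing.assert_allclose(
            glcm(img, direction, levels=6), glcm(flipped, direction, levels=6)
        )


class TestGlcmStats:
    def test_diagonal_unit_mass(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        s = glcm_stats(P)
        assert s.as_tuple() == pytest.approx((1.0, 0.0, 1.0, 0.0))

    def test_checkerboard_hand_computation(self):
        s = glcm_stats(glcm(CHECKERBOARD, 0, levels=2))
        assert s.energy == pytest.approx(0.5)
        assert s.contrast == pytest.approx(1.0)
        assert s.homogeneity == pytest.approx(0.5)
        assert s.entropy == pytest.approx(np.log(2))

    def test_uniform_matrix_closed_form(self):
        L = 5
        s = glcm_stats(np.full((L, L), 1.0 / L**2))
        assert s.energy == pytest.approx(1.0 / L**2)
        assert s.entropy == pytest.approx(2 * np.log(L))

    def test_unnormalised_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            glcm_stats(np.ones((3, 3)))

    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(3, 8), st.integers(3, 8)),
            elements=st.integers(0, 5),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_statistic_bounds(self, img):
        L = 6
        for d in DIRECTIONS_DEG:
            s = glcm_stats(glcm(img, d, levels=L))
            assert 0 < s.energy <= 1
            assert s.contrast >= 0
            assert 0 < s.homogeneity <= 1
            assert 0 <= s.entropy <= 2 * np.log(L) + 1e-12


class TestTextureFeatures:
    def _stack(self, rng, n_bands):
        wl = np.linspace(975, 1645, n_bands)
        return rng.uniform(20, 60, size=(12, 12, n_bands)), wl

    def test_seven_wavelengths_give_28_features(self, rng):
        stack, wl = self._stack(rng, 20)
        feats = texture_features(stack, wl, wl[[1, 4, 7, 9, 12, 15, 18]])
        assert len(feats) == 28

    def test_single_wavelength_gives_four(self, rng):
        stack, wl = self._stack(rng, 5)
        assert len(texture_features(stack, wl, [wl[2]])) == 4

    def test_unknown_wavelength_rejected(self, rng):
        stack, wl = self._stack(rng, 5)
        with pytest.raises(ValueError, match="not present"):
            texture_features(stack, wl, [1234.5])

    def test_direction_mean_matches_explicit_loop(self, rng):
        stack, wl = self._stack(rng, 3)
        feats = texture_features(stack, wl, [wl[1]])
        q = quantize(stack[:, :, 1], 64)
        contrasts = [glcm_stats(glcm(q, d, levels=64)).contrast for d in DIRECTIONS_DEG]
        assert feats[f"contrast_{wl[1]:.1f}"] == pytest.approx(np.mean(contrasts))

    def test_flat_field_degenerate_texture(self):
        stack = np.full((8, 8, 2), 33.0)
        feats = texture_features(stack, np.array([1000.0, 1100.0]), [1000.0])
        assert feats["energy_1000.0"] == pytest.approx(1.0)
        assert feats["entropy_1000.0"] == pytest.approx(0.0)


def test_smoother_fields_look_smoother_to_glcm():
    """Longer correlation length -> higher energy/homogeneity, lower
    contrast/entropy (median over 20 replicate fields)."""
    stats = {1.0: [], 10.0: []}
    for corr, bucket in stats.items():
        for seed in range(20):
            field = correlated_field(50, corr, np.random.default_rng(1000 + seed))
            q = quantize(field, 64)
            per_dir = [glcm_stats(glcm(q, d, levels=64)) for d in DIRECTIONS_DEG]
            bucket.append(
                tuple(np.mean([getattr(s, n) for s in per_dir]) for n in
                      ("energy", "contrast", "homogeneity", "entropy"))
            )
    rough = np.median(np.array(stats[1.0]), axis=0)
    smooth = np.median(np.array(stats[10.0]), axis=0)
    assert smooth[0] > rough[0]      # energy
    assert smooth[1] < rough[1]      # contrast
    assert smooth[2] > rough[2]      # homogeneity
    assert smooth[3] < rough[3]      # entropy
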