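"""Conspicuity channels: pyramids, normalization, Gabor bank, local entropy."""

import numpy as np
import pytest

from historoi.conspicuity import (
    SMALL_PYRAMID,
    PyramidConfig,
    _gabor_bank,
    all_conspicuity_maps,
    center_surround_maps,
    conspicuity,
    entropy_conspicuity,
    gabor_magnitude,
    gaussian_pyramid,
    intensity_channel,
    local_entropy,
    normalize_map,
    orientation_angles,
)
from historoi.fixtures import FixtureSpec, generate_fixture
from oracles import (
    brute_force_convolve,
    brute_force_entropy,
    gaussian_kernel_1d,
    local_maxima_naive,
)


class TestIntensityChannel:
    def test_white_maps_to_one(self):
        img = np.ones((16, 16, 3))
        assert np.allclose(intensity_channel(img), 1.0)

    def test_constant_rgb_gives_channel_mean(self):
        img = np.empty((16, 16, 3))
        img[..., 0], img[..., 1], img[..., 2] = 0.3, 0.6, 0.9
        assert np.allclose(intensity_channel(img), 0.6)

    def test_fixture_range(self):
        img, _ = generate_fixture(FixtureSpec(seed=2))
        i = intensity_channel(img)
        assert i.min() >= 0 and i.max() <= 1


class TestCenterSurround:
    def test_constant_image_all_zero_maps(self):
        maps = center_surround_maps(np.full((64, 64), 0.7), SMALL_PYRAMID)
        assert len(maps) == len(SMALL_PYRAMID.center_levels) * len(SMALL_PYRAMID.surround_deltas)
        for m in maps:
            assert np.allclose(m, 0.0)

    def test_single_bright_pixel_peaks_at_its_location(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        cfg = PyramidConfig(n_levels=4, center_levels=(1,), surround_deltas=(2,))
        m = center_surround_maps(img, cfg)[0]
        peak = np.unravel_index(np.argmax(m), m.shape)
        # centre level 1 halves coordinates; peak must be at/adjacent to (16, 16)
        assert abs(peak[0] - 16) <= 1 and abs(peak[1] - 16) <= 1

    def test_matches_two_scale_gaussian_difference_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(32, 32))
        cfg = PyramidConfig(n_levels=3, center_levels=(0,), surround_deltas=(2,))
        got = center_surround_maps(img, cfg)[0]
        # oracle: two explicit smooth+decimate steps, then nearest upsampling
        radius = int(4.0 * 1.0 + 0.5)
        k1 = gaussian_kernel_1d(1.0, radius)
        kernel = np.outer(k1, k1)
        level = img
        for _ in range(2):
            level = brute_force_convolve(level, kernel)[::2, ::2]
        up = np.repeat(np.repeat(level, 4, axis=0), 4, axis=1)[:32, :32]
        expected = np.abs(img - up)
        assert np.allclose(got, expected, atol=1e-6)

    def test_image_too_small_for_pyramid_raises(self):
        with pytest.raises(ValueError):
            gaussian_pyramid(np.zeros((4, 4)), n_levels=8)


class TestNormalizeMap:
    def test_all_zero_passthrough(self):
        assert np.allclose(normalize_map(np.zeros((16, 16))), 0.0)

    def test_single_peak_preserved_at_unit_scale(self):
        m = np.zeros((16, 16))
        m[5, 5] = 0.7
        out = normalize_map(m)
        assert out.max() == pytest.approx(1.0)

    def test_two_equal_peaks_suppressed_to_zero(self):
        m = np.zeros((16, 16))
        m[3, 3] = 1.0
        m[10, 12] = 1.0
        assert np.allclose(normalize_map(m), 0.0)

    def test_factor_matches_naive_local_maxima_enumeration(self, rng):
        m = rng.uniform(size=(16, 16))
        m[m < 0.7] = 0.0  # sparse peaks
        out = normalize_map(m)
        values = sorted(local_maxima_naive(m / m.max()), reverse=True)
        mbar = np.mean(values[1:]) if len(values) > 1 else 0.0
        expected = (m / m.max()) * (1.0 - mbar) ** 2
        assert np.allclose(out, expected, atol=1e-12)


class TestConspicuity:
    @pytest.mark.parametrize("channel", ["intensity", "color", "orientation"])
    def test_constant_image_gives_zero_map(self, channel):
        img = np.full((64, 64, 3), 0.5)
        assert np.allclose(conspicuity(img, channel), 0.0)

    def test_hue_disc_seen_by_color_not_intensity(self):
        img = np.full((64, 64, 3), 0.5)
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10 ** 2
        # equal intensity, opposite hue balance
        img[disc] = (0.7, 0.5, 0.3)
        cmap = conspicuity(img, "color")
        imap = conspicuity(img, "intensity")
        assert cmap[disc].mean() > 0.05
        assert imap.max() <= 0.2 or imap[disc].mean() < cmap[disc].mean() / 5

    def test_vertical_bar_maximal_in_vertical_gabor_channel(self):
        bar = np.zeros((32, 32))
        bar[:, 15:17] = 1.0
        responses = [gabor_magnitude(bar, kern)[16, 16] for kern in _gabor_bank(4)]
        angles = orientation_angles(4)
        assert angles[int(np.argmax(responses))] == 90.0

    def test_gabor_matches_brute_force_convolution(self, rng):
        img = rng.uniform(size=(32, 32))
        kernel = _gabor_bank(4)[1]
        got = gabor_magnitude(img, kernel)
        expected = np.hypot(brute_force_convolve(img, np.real(kernel)),
                            brute_force_convolve(img, np.imag(kernel)))
        assert np.allclose(got, expected, atol=1e-6)

    def test_maps_lie_in_unit_interval(self):
        img, _ = generate_fixture(FixtureSpec(seed=9))
        for name, m in all_conspicuity_maps(img).items():
            assert m.shape == img.shape[:2]
            assert m.min() >= 0.0 and m.max() <= 1.0, name

    def test_entropy_map_is_shift_equivariant(self):
        img, _ = generate_fixture(FixtureSpec(seed=4))
        shifted = np.roll(img, 16, axis=1)
        e1 = entropy_conspicuity(img)
        e2 = entropy_conspicuity(shifted)
        sl = np.s_[:, 24:-24]
        assert np.allclose(np.roll(e1, 16, axis=1)[sl], e2[sl], atol=1e-12)

    def test_intensity_map_shift_equivariant_for_dyadic_shift(self, rng):
        # constant background, one textured patch; shifting the patch by a
        # multiple of the coarsest pyramid stride shifts the map (borders
        # contribute only through Gaussian tails, hence the loose tolerance)
        img = np.full((64, 128, 3), 0.6)
        img[22:42, 30:50] = 0.35 + rng.uniform(-0.1, 0.1, (20, 20, 1))
        shift = 32
        shifted = np.roll(img, shift, axis=1)
        m1 = conspicuity(img, "intensity")
        m2 = conspicuity(shifted, "intensity")
        assert np.allclose(np.roll(m1, shift, axis=1), m2, atol=0.02)


class TestLocalEntropy:
    def test_constant_image_zero_entropy(self):
        assert np.allclose(entropy_conspicuity(np.full((32, 32, 3), 0.3)), 0.0)

    def test_checkerboard_even_window_is_exactly_one_bit(self):
        img = (np.indices((16, 16)).sum(axis=0) % 2).astype(float)
        ent = local_entropy(img, window=4, n_bins=2)
        assert np.allclose(ent[4:-4, 4:-4], 1.0)

    def test_matches_brute_force_histogram_entropy(self, rng):
        img = rng.uniform(size=(24, 24))
        got = local_entropy(img, window=5, n_bins=8)
        expected = brute_force_entropy(img, window=5, n_bins=8)
        assert np.allclose(got, expected, atol=1e-9)

    def test_islet_entropy_exceeds_background(self):
        img, mask = generate_fixture(FixtureSpec(seed=6))
        ent = entropy_conspicuity(img, window=9)
        assert ent[mask > 0].mean() > ent[mask == 0].mean()

    @pytest.mark.parametrize("kwargs", [dict(window=1), dict(n_bins=1)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            local_entropy(np.zeros((8, 8)), **{"window": 5, "n_bins": 4, **kwargs})


def test_pyramid_config_validation():
    with pytest.raises(ValueError):
        PyramidConfig(n_levels=4, center_levels=(2,), surround_deltas=(3,)).validate()
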