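"""K-space artifact pipeline: transforms, zero-filling, merging, datasets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motioncorr import evalstats, kspace, phantom
from motioncorr.kspace import (MotionPattern, TRAIN_PATTERNS, TEST_PATTERNS,
                               build_paired_dataset, fft2c, ifft2c_mag,
                               merge_halves, nominal_pair_count, rotate_image,
                               simulate_motion, zero_fill_lines)


@pytest.fixture(scope="module")
def slice64():
    return phantom.generate_phantom_volume(3, 3, (64, 64)).slices[1]


class TestRotate:
    def test_zero_angle_is_identity(self, slice64):
        np.testing.assert_array_equal(rotate_image(slice64, 0.0), slice64)

    def test_rotation_inverse_pair_small_interior_error(self, slice64):
        back = rotate_image(rotate_image(slice64, 2.0), -2.0)
        interior = np.s_[8:-8, 8:-8]
        # bilinear resampling smooths tissue edges twice; the mean interior
        # error stays at the few-percent interpolation level
        assert np.abs(back[interior] - slice64[interior]).mean() < 0.03

    def test_point_rotates_to_analytic_coordinate(self):
        img = np.zeros((64, 64))
        img[20, 40] = 1.0
        out = rotate_image(img, 10.0)
        got = np.array(np.unravel_index(np.argmax(out), out.shape), float)
        center = np.array([31.5, 31.5])
        th = np.deg2rad(10.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected = center + rot @ (np.array([20.0, 40.0]) - center)
        assert np.linalg.norm(got - expected) < 1.0


class TestFFT:
    def test_constant_image_concentrates_at_dc(self):
        k = fft2c(np.full((16, 16), 3.0))
        dc = np.abs(k[8, 8])
        assert dc > 0
        off = np.abs(k).sum() - dc
        assert off < 1e-9 * dc

    def test_round_trip(self, slice64):
        np.testing.assert_allclose(ifft2c_mag(fft2c(slice64)), slice64,
                                   atol=1e-12)

    def test_parseval_orthonormal(self, slice64):
        k = fft2c(slice64)
        assert np.isclose((slice64 ** 2).sum(), (np.abs(k) ** 2).sum())

    def test_zero_spectrum_gives_zero_image(self):
        np.testing.assert_array_equal(
            ifft2c_mag(np.zeros((8, 8), complex)), np.zeros((8, 8)))


class TestZeroFill:
    def test_none_and_zero_are_identity(self, slice64):
        k = fft2c(slice64)
        np.testing.assert_array_equal(zero_fill_lines(k, None), k)
        np.testing.assert_array_equal(zero_fill_lines(k, 0), k)

    def test_interval_10_on_256_rows_zeroes_25_rows_dc_exempt(self):
        k = np.ones((256, 256), complex)
        out = zero_fill_lines(k, 10)
        zeroed = int((np.abs(out).sum(axis=1) == 0).sum())
        # brute-force enumeration: DC-at-origin rows {0,10,...,250} minus DC
        expected = len([r for r in range(0, 256, 10) if r != 0])
        assert expected == 25
        assert zeroed == expected
        # without the DC exemption all 26 rows go
        out_all = zero_fill_lines(k, 10, exempt_dc=False)
        assert int((np.abs(out_all).sum(axis=1) == 0).sum()) == 26

    def test_energy_never_increases(self, slice64):
        k = fft2c(slice64)
        for interval in (10, 20, 30):
            out = zero_fill_lines(k, interval)
            assert (np.abs(out) ** 2).sum() <= (np.abs(k) ** 2).sum()

    def test_smaller_interval_removes_more_energy(self, slice64):
        k = fft2c(slice64)
        energies = [(np.abs(zero_fill_lines(k, i)) ** 2).sum()
                    for i in (10, 20, 30)]
        assert energies[0] <= energies[1] <= energies[2]

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            zero_fill_lines(np.zeros((8, 8), complex), -5)


class TestMerge:
    def test_self_merge_identity(self, slice64):
        k = fft2c(slice64)
        np.testing.assert_array_equal(merge_halves(k, k), k)

    def test_halves_taken_by_definition(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        b = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        m = merge_halves(a, b)
        np.testing.assert_array_equal(m[:8], a[:8])
        np.testing.assert_array_equal(m[8:], b[8:])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_halves(np.zeros((8, 8), complex), np.zeros((8, 4), complex))

    def test_merged_spectra_produce_ghosting(self, slice64):
        left = rotate_image(slice64, 3.0)
        right = rotate_image(slice64, -3.0)
        out = ifft2c_mag(merge_halves(fft2c(left), fft2c(right)))
        assert np.all(out >= 0)
        assert np.abs(out - left).max() > 1e-3
        assert np.abs(out - right).max() > 1e-3

    def test_zero_fill_commutes_with_merge(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 12)) + 1j * rng.normal(size=(20, 12))
        b = rng.normal(size=(20, 12)) + 1j * rng.normal(size=(20, 12))
        for interval in (2, 5):
            first = merge_halves(zero_fill_lines(a, interval),
                                 zero_fill_lines(b, interval))
            second = zero_fill_lines(merge_halves(a, b), interval)
            np.testing.assert_allclose(first, second)


class TestSimulate:
    def test_identity_pattern_is_exact(self, slice64):
        out = simulate_motion(slice64, MotionPattern(0, None))
        np.testing.assert_array_equal(out, slice64)
        assert evalstats.ssim(out, slice64) == 1.0

    def test_zero_rotation_with_zero_fill_still_degrades(self, slice64):
        out = simulate_motion(slice64, MotionPattern(0, 10))
        assert evalstats.ssim(out, slice64) < 1.0

    def test_deterministic(self, slice64):
        p = MotionPattern(2, 20)
        np.testing.assert_array_equal(simulate_motion(slice64, p),
                                      simulate_motion(slice64, p))

    def test_output_shape_and_nonnegativity(self, slice64):
        out = simulate_motion(slice64, MotionPattern(3, 10))
        assert out.shape == slice64.shape
        assert np.all(out >= 0) and np.all(np.isfinite(out))

    def test_ssim_monotone_over_trained_grid(self, slice64):
        """Stronger motion (larger RA, smaller KI) never raises SSIM."""
        kis = [None, 30, 20, 10]
        ras = [0, 1, 2, 3]
        table = {(ra, ki): evalstats.ssim(
            simulate_motion(slice64, MotionPattern(ra, ki)), slice64)
            for ra in ras for ki in kis}
        for ki in kis:
            col = [table[(ra, ki)] for ra in ras]
            assert all(a >= b for a, b in zip(col, col[1:])), (ki, col)
        for ra in ras:
            row = [table[(ra, ki)] for ki in kis]
            assert all(a >= b for a, b in zip(row, row[1:])), (ra, row)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            MotionPattern(-1, 10)
        with pytest.raises(ValueError):
            MotionPattern(1, -10)


class TestDataset:
    def test_pattern_grids(self):
        assert len(TRAIN_PATTERNS) == 16
        assert len({p.label for p in TRAIN_PATTERNS}) == 16
        assert {p.label for p in TEST_PATTERNS} == {
            "0_none", "1_30", "2_20", "3_10", "1.5_25", "2.5_15"}

    def test_nominal_pair_count_formula(self):
        assert nominal_pair_count(51, 176, 16, 3) == 47872

    def test_one_volume_six_slices_stride3_gives_32_pairs(self):
        vol = phantom.generate_phantom_volume(5, 6, (32, 32))
        pairs = build_paired_dataset([vol], TRAIN_PATTERNS, slice_stride=3)
        assert len(pairs) == 32      # 2 retained slices x 16 patterns
        assert {p.slice_index for p in pairs} == {0, 3}

    def test_stride_one_single_pattern_gives_n_slices_pairs(self):
        vol = phantom.generate_phantom_volume(5, 4, (32, 32))
        pairs = build_paired_dataset([vol], [MotionPattern(1, 30)], 1)
        assert len(pairs) == 4

    def test_empty_inputs_rejected(self):
        vol = phantom.generate_phantom_volume(5, 2, (32, 32))
        with pytest.raises(ValueError):
            build_paired_dataset([], TRAIN_PATTERNS, 1)
        with pytest.raises(ValueError):
            build_paired_dataset([vol], [], 1)
        with pytest.raises(ValueError):
            build_paired_dataset([vol], TRAIN_PATTERNS, 0)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=1, max_value=40))
def test_zero_fill_preserves_shape_and_bounds_energy(interval):
    rng = np.random.default_rng(interval)
    k = rng.normal(size=(40, 24)) + 1j * rng.normal(size=(40, 24))
    out = zero_fill_lines(k, interval)
    assert out.shape == k.shape
    assert (np.abs(out) ** 2).sum() <= (np.abs(k) ** 2).sum() + 1e-9
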