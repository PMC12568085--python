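"""Fourier-domain length normalization and initial-point normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eyewrite import (FilterConfig, NormalizationConfig, Sample, Trajectory,
                      dft, initial_point_normalize, normalize_length,
                      pad_spectrum, preprocess, truncate_spectrum,
                      zero_pad_baseline)


def _brute_force_dft(x):
    L = len(x)
    n = np.arange(L)
    return np.array([np.sum(x * np.exp(-2j * np.pi * k * n / L))
                     for k in range(L)])


class TestDft:
    def test_constant_signal_is_dc_only(self):
        np.testing.assert_allclose(dft(np.full(4, 2.5)),
                                   [10.0, 0, 0, 0], atol=1e-12)

    def test_unit_impulse_is_flat(self):
        x = np.zeros(8)
        x[0] = 1.0
        np.testing.assert_allclose(dft(x), np.ones(8), atol=1e-12)

    def test_matches_direct_summation(self, rng):
        x = rng.normal(size=16)
        np.testing.assert_allclose(dft(x), _brute_force_dft(x), atol=1e-9)

    def test_hermitian_symmetry_for_real_input(self, rng):
        X = dft(rng.normal(size=15))
        np.testing.assert_allclose(X[1:], np.conj(X[1:][::-1]), atol=1e-9)


class TestTruncateSpectrum:
    def test_kept_bins_l8_m4(self):
        X = np.arange(8, dtype=complex)
        np.testing.assert_array_equal(truncate_spectrum(X, 4),
                                      X[[0, 1, 6, 7]])

    def test_pure_cosine_bins_survive(self):
        # 1-cycle cosine at L=32 lives in bins 1 and 31; truncation to
        # M=8 must carry both (to positions 1 and 7)
        x = np.cos(2 * np.pi * np.arange(32) / 32)
        Xd = truncate_spectrum(dft(x), 8)
        np.testing.assert_allclose(Xd[1], 16.0, atol=1e-9)
        np.testing.assert_allclose(Xd[7], 16.0, atol=1e-9)
        mask = np.ones(8, bool)
        mask[[1, 7]] = False
        np.testing.assert_allclose(Xd[mask], 0, atol=1e-9)

    def test_m_not_below_l_rejected(self):
        with pytest.raises(ValueError, match="M < L"):
            truncate_spectrum(np.ones(4, complex), 4)


class TestPadSpectrum:
    def test_l4_m8_placement(self):
        a, b, c, d = 1 + 1j, 2.0, 3 - 1j, 4.0
        np.testing.assert_array_equal(
            pad_spectrum(np.array([a, b, c, d]), 8),
            [a, b, 0, 0, 0, 0, c, d])

    def test_zero_spectrum_stays_zero(self):
        np.testing.assert_array_equal(pad_spectrum(np.zeros(5, complex), 11),
                                      np.zeros(11))

    def test_pad_then_truncate_recovers_odd_length(self, rng):
        X = rng.normal(size=7) + 1j * rng.normal(size=7)
        np.testing.assert_allclose(truncate_spectrum(pad_spectrum(X, 16), 7),
                                   X, atol=1e-12)

    def test_m_not_above_l_rejected(self):
        with pytest.raises(ValueError, match="M > L"):
            pad_spectrum(np.ones(4, complex), 4)


class TestNormalizeLength:
    CFG = NormalizationConfig(target_length=64)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=2, max_value=10_000))
    def test_output_length_always_m(self, L):
        rng = np.random.default_rng(L)
        traj = Trajectory(points=rng.normal(size=(L, 2)))
        assert normalize_length(traj, self.CFG).n == 64

    def test_identity_when_m_equals_l(self, rng):
        pts = rng.normal(size=(64, 2))
        out = normalize_length(Trajectory(points=pts), self.CFG)
        np.testing.assert_allclose(out.points, pts, atol=1e-9)

    def test_bandlimited_cosine_closed_form(self):
        # cos(2 pi 2 n / 32) resampled 32 -> 16 is exactly cos(2 pi 2 n / 16)
        n32 = np.arange(32)
        x = np.cos(2 * np.pi * 2 * n32 / 32)
        traj = Trajectory(points=np.column_stack([x, np.zeros(32)]))
        out = normalize_length(traj, NormalizationConfig(target_length=16))
        n16 = np.arange(16)
        np.testing.assert_allclose(out.points[:, 0],
                                   np.cos(2 * np.pi * 2 * n16 / 16),
                                   atol=1e-9)

    @pytest.mark.parametrize("L", [5, 64, 333])
    def test_constant_preserved_at_any_length(self, L):
        traj = Trajectory(points=np.tile([2.0, -3.0], (L, 1)))
        out = normalize_length(traj, self.CFG)
        np.testing.assert_allclose(out.points, np.tile([2.0, -3.0], (64, 1)),
                                   atol=1e-9)

    def test_literal_mode_scales_with_l_over_m(self):
        traj = Trajectory(points=np.tile([2.0, 0.0], (128, 1)))
        out = normalize_length(
            traj, NormalizationConfig(target_length=64,
                                      amplitude_mode="literal"))
        np.testing.assert_allclose(out.points[:, 0], 4.0, atol=1e-9)

    def test_truncation_energy_monotone(self, rng):
        x = rng.normal(size=500)
        X = dft(x)
        Xd = truncate_spectrum(X, 64)
        assert np.sum(np.abs(Xd) ** 2) <= np.sum(np.abs(X) ** 2) + 1e-9

    def test_imaginary_residue_small(self, rng):
        # Hermitian bookkeeping: for odd target lengths the retained bins
        # pair up exactly, so the inverse transform of a real signal's
        # edited spectrum is real to rounding error
        x = rng.normal(size=501)
        Xd = truncate_spectrum(dft(x), 63)
        resid = np.abs(np.fft.ifft(Xd).imag).max()
        assert resid <= 1e-6 * np.sqrt(np.mean(x ** 2))

    def test_imaginary_residue_small_even_m_bandlimited(self):
        # even target lengths split a conjugate pair at the new Nyquist
        # bin; when the signal has no content there the residue vanishes
        n = np.arange(500)
        x = np.cos(2 * np.pi * 9 * n / 500 + 1.0)
        Xd = truncate_spectrum(dft(x), 64)
        resid = np.abs(np.fft.ifft(Xd).imag).max()
        assert resid <= 1e-6 * np.sqrt(np.mean(x ** 2))

    def test_lowfreq_signal_matches_ideal_resampling(self):
        # a sum of tones below the retained band resamples exactly
        L, M = 200, 50
        n = np.arange(L)
        x = (1.2 * np.cos(2 * np.pi * 3 * n / L + 0.4)
             + 0.7 * np.sin(2 * np.pi * 7 * n / L))
        m = np.arange(M)
        expected = (1.2 * np.cos(2 * np.pi * 3 * m / M + 0.4)
                    + 0.7 * np.sin(2 * np.pi * 7 * m / M))
        traj = Trajectory(points=np.column_stack([x, x]))
        out = normalize_length(traj, NormalizationConfig(target_length=M))
        np.testing.assert_allclose(out.points[:, 0], expected, atol=1e-6)

    def test_centered_literal_convention_differs(self, rng):
        x = rng.normal(size=100)
        traj = Trajectory(points=np.column_stack([x, x]))
        a = normalize_length(traj, NormalizationConfig(target_length=32))
        b = normalize_length(
            traj, NormalizationConfig(target_length=32,
                                      truncation_convention="centered_literal"))
        assert not np.allclose(a.points, b.points)


class TestInitialPointNormalize:
    def test_direct_subtraction(self):
        out = initial_point_normalize(
            Trajectory(points=np.array([[3.0, 4.0], [5.0, 6.0]])))
        np.testing.assert_array_equal(out.points, [[0, 0], [2, 2]])

    def test_idempotent(self, rng):
        traj = Trajectory(points=rng.normal(size=(20, 2)))
        once = initial_point_normalize(traj)
        twice = initial_point_normalize(once)
        np.testing.assert_array_equal(once.points, twice.points)

    def test_single_point(self):
        out = initial_point_normalize(
            Trajectory(points=np.array([[7.0, -2.0]])))
        np.testing.assert_array_equal(out.points, [[0, 0]])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_displacements_preserved(self, seed):
        pts = np.random.default_rng(seed).normal(size=(15, 2)) * 100
        out = initial_point_normalize(Trajectory(points=pts))
        np.testing.assert_allclose(np.diff(out.points, axis=0),
                                   np.diff(pts, axis=0),
                                   rtol=0, atol=1e-9)


class TestZeroPadBaseline:
    def test_pads_with_origin_points(self):
        traj = Trajectory(points=np.ones((3, 2)))
        out = zero_pad_baseline(traj, 5)
        np.testing.assert_array_equal(out.points[:3], np.ones((3, 2)))
        np.testing.assert_array_equal(out.points[3:], np.zeros((2, 2)))

    def test_equal_length_is_identity(self, rng):
        pts = rng.normal(size=(10, 2))
        out = zero_pad_baseline(Trajectory(points=pts), 10)
        np.testing.assert_array_equal(out.points, pts)

    def test_longer_input_rejected(self):
        with pytest.raises(ValueError, match="without truncation"):
            zero_pad_baseline(Trajectory(points=np.zeros((513, 2))), 512)


class TestPreprocessPipeline:
    def test_webcam_path(self, rng):
        s = Sample(Trajectory(points=rng.normal(size=(300, 2)) + 5.0),
                   "0", "s1")
        out = preprocess(s, FilterConfig.disabled(), NormalizationConfig())
        assert out.trajectory.n == 64
        np.testing.assert_array_equal(out.trajectory.points[0], [0, 0])
        assert out.label == "0" and out.subject_id == "s1"

    def test_baseline_path_skips_dft_and_ip(self, rng):
        pts = rng.normal(size=(100, 2))
        s = Sample(Trajectory(points=pts), "0", "s1")
        out = preprocess(s, FilterConfig.disabled(),
                         NormalizationConfig(baseline_pad_length=512))
        assert out.trajectory.n == 512
        np.testing.assert_array_equal(out.trajectory.points[:100], pts)

    def test_full_eog_chain_annihilates_constants(self):
        s = Sample(Trajectory(points=np.tile([4.0, -2.0], (3000, 1))),
                   "0", "s1")
        out = preprocess(s, FilterConfig(), NormalizationConfig())
        assert out.trajectory.n == 64
        assert np.abs(out.trajectory.points).max() < 1e-5
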