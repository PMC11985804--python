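"""Preprocessing: trimming, referencing, FIR design and segmentation."""

import numpy as np
import pytest

from docfc import preprocess
from docfc.preprocess import (FilterKernel, WindowGrid, apply_zero_phase,
                              average_reference, band_decompose,
                              broadband_clean, design_fir_bandpass,
                              design_fir_notch, measure_fir_figures, segment,
                              trim_edges, truncate_to_count)
from docfc.types import CANONICAL_BANDS, Recording


def _rec(samples, fs=256.0):
    labels = tuple(f"CH{i}" for i in range(samples.shape[0]))
    return Recording(samples=samples, fs=fs, channel_labels=labels)


class TestTrimAndReference:
    def test_trim_removes_two_minutes_each_side(self, rng):
        rec = _rec(rng.standard_normal((3, 1800 * 256)))
        out = trim_edges(rec, 120.0)
        assert out.duration_s == pytest.approx(1560.0)
        np.testing.assert_array_equal(
            out.samples, rec.samples[:, 120 * 256:-120 * 256])

    def test_trim_zero_is_identity(self, rng):
        rec = _rec(rng.standard_normal((2, 4000)))
        np.testing.assert_array_equal(trim_edges(rec, 0.0).samples,
                                      rec.samples)

    def test_trim_too_short_raises(self, rng):
        rec = _rec(rng.standard_normal((2, 200 * 256)))
        with pytest.raises(ValueError, match="too short"):
            trim_edges(rec, 120.0)

    def test_average_reference_zeroes_cross_channel_mean(self, rng):
        rec = _rec(rng.standard_normal((5, 2000)) + 3.0)
        out = average_reference(rec)
        np.testing.assert_allclose(out.samples.mean(axis=0), 0.0, atol=1e-12)

    def test_average_reference_offset_invariance_and_idempotence(self, rng):
        x = rng.standard_normal((4, 1000))
        shifted = average_reference(_rec(x + 7.5))
        plain = average_reference(_rec(x))
        np.testing.assert_allclose(shifted.samples, plain.samples, atol=1e-10)
        again = average_reference(plain)
        np.testing.assert_allclose(again.samples, plain.samples, atol=1e-12)

    def test_average_reference_single_channel_raises(self, rng):
        with pytest.raises(ValueError):
            average_reference(_rec(rng.standard_normal((1, 100))))


class TestFIRDesign:
    def test_kernel_is_linear_phase(self):
        k = design_fir_bandpass(8.0, 13.0, 256.0)
        np.testing.assert_allclose(k.coefficients, k.coefficients[::-1])

    def test_asymmetric_kernel_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            FilterKernel(np.array([1.0, 2.0, 3.0]), design="bad")

    @pytest.mark.parametrize("band", CANONICAL_BANDS[2:4], ids=lambda b: b.name)
    def test_hamming_design_figures(self, band):
        """Mid-spectrum bands hit the canonical Hamming figures of merit."""
        k = design_fir_bandpass(band.lo, band.hi, 256.0)
        tb_lo = min(max(0.25 * band.lo, 2.0), band.lo)
        tb_hi = min(max(0.25 * band.hi, 2.0), 128.0 - band.hi)
        att, rip = measure_fir_figures(
            k, 256.0, band.lo, band.hi, band.lo - tb_lo, band.hi + tb_hi)
        assert abs(att - 53.0) < 2.0
        assert abs(rip - 0.0194) < 0.015

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            design_fir_bandpass(8.0, 200.0, 256.0)
        with pytest.raises(ValueError):
            design_fir_bandpass(0.0, 13.0, 256.0)

    def test_zero_phase_tone_at_zero_lag(self):
        fs, f = 256.0, 10.0
        t = np.arange(int(20 * fs)) / fs
        x = np.cos(2 * np.pi * f * t)
        k = design_fir_bandpass(8.0, 13.0, fs)
        y = apply_zero_phase(k, x)[0]
        sl = slice(int(2 * fs), int(18 * fs))  # away from edges
        lags = np.arange(-50, 51)
        xc = [np.dot(x[sl], np.roll(y, lag)[sl]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0


class TestBroadbandClean:
    fs = 256.0

    def _tone(self, f, dur=30.0, nch=2):
        t = np.arange(int(dur * self.fs)) / self.fs
        return _rec(np.tile(np.sin(2 * np.pi * f * t), (nch, 1)), self.fs)

    def _rms_mid(self, x):
        n = x.shape[-1]
        return float(np.sqrt(np.mean(x[..., n // 4:-n // 4] ** 2)))

    def test_mains_tone_suppressed(self):
        rec = self._tone(50.0)
        out = broadband_clean(rec)
        assert self._rms_mid(out.samples) <= 0.01 * self._rms_mid(rec.samples)

    def test_passband_tone_preserved(self):
        rec = self._tone(10.0)
        out = broadband_clean(rec)
        ratio = self._rms_mid(out.samples) / self._rms_mid(rec.samples)
        assert abs(ratio - 1.0) < 0.05

    def test_dc_offset_removed(self, rng):
        rec = _rec(np.full((2, int(30 * self.fs)), 25.0), self.fs)
        out = broadband_clean(rec)
        assert self._rms_mid(out.samples) < 0.25  # 1% of the 25 uV offset

    def test_low_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            broadband_clean(_rec(rng.standard_normal((2, 4000)), fs=100.0))


class TestBandDecompose:
    fs = 256.0

    def test_tone_lands_in_its_band_only(self):
        t = np.arange(int(30 * self.fs)) / self.fs
        rec = _rec(np.tile(np.cos(2 * np.pi * 10.0 * t), (2, 1)), self.fs)
        out = band_decompose(rec)
        mid = slice(int(5 * self.fs), int(25 * self.fs))
        rms_in = np.sqrt(np.mean(out["alpha"].samples[:, mid] ** 2))
        rms_ref = np.sqrt(np.mean(rec.samples[:, mid] ** 2))
        rms_out = np.sqrt(np.mean(out["delta"].samples[:, mid] ** 2))
        assert abs(rms_in / rms_ref - 1.0) < 0.05
        assert rms_out / rms_ref <= 0.01

    def test_band_powers_bounded_by_broadband(self, rng):
        rec = _rec(rng.standard_normal((2, int(30 * self.fs))), self.fs)
        out = band_decompose(rec)
        total = sum(np.mean(r.samples ** 2) for r in out.values())
        assert total <= np.mean(rec.samples ** 2)

    def test_band_above_nyquist_rejected(self, rng):
        from docfc.types import BandSpec
        rec = _rec(rng.standard_normal((2, 4000)), fs=64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            band_decompose(rec, (BandSpec("gamma", 30.0, 48.0),))


class TestSegmentation:
    @pytest.mark.parametrize("T_s,window_s,expected_K", [
        (960, 20, 95), (968, 16, 120), (40, 20, 3),
    ])
    def test_window_count(self, rng, T_s, window_s, expected_K):
        fs = 256.0
        x = rng.standard_normal(int(T_s * fs))
        windows, grid = segment(x, fs, window_s)
        assert grid.K == expected_K
        assert windows.shape == (expected_K, int(window_s * fs))

    def test_window_count_matches_bruteforce_enumeration(self, rng):
        fs = 10.0
        for n in [100, 137, 205]:
            x = rng.standard_normal(n)
            _, grid = segment(x, fs, 4.0)
            W, S = grid.W, grid.S
            brute = sum(1 for s in range(0, n, S) if s + W <= n
                        and s % S == 0)
            assert grid.K == brute

    def test_even_windows_tile_the_signal(self, rng):
        x = rng.standard_normal(1000)
        windows, grid = segment(x, 10.0, 10.0)  # W=100, S=50
        even = windows[::2].ravel()
        np.testing.assert_array_equal(even, x[:len(even)])

    def test_window_longer_than_signal_raises(self, rng):
        with pytest.raises(ValueError):
            segment(rng.standard_normal(100), 10.0, 20.0)

    def test_window_starts_are_multiples_of_step(self, rng):
        _, grid = segment(rng.standard_normal(1234), 10.0, 8.0)
        np.testing.assert_array_equal(grid.starts() % grid.S, 0)

    @pytest.mark.parametrize("K_target,window_s,expected_s", [
        (95, 20, 960), (1, 20, 20), (120, 16, 968),
    ])
    def test_truncate_to_count_length(self, rng, K_target, window_s,
                                      expected_s):
        fs = 256.0
        x = rng.standard_normal(int(1000 * fs))
        y = truncate_to_count(x, fs, window_s, 0.5, K_target)
        assert y.shape[-1] == int(expected_s * fs)
        _, grid = segment(y, fs, window_s)
        assert grid.K == K_target

    def test_truncate_beyond_available_raises(self, rng):
        with pytest.raises(ValueError):
            truncate_to_count(rng.standard_normal(100), 10.0, 4.0, 0.5, 50)

    def test_annotation_mask_drops_overlapping_windows(self, rng):
        from docfc.preprocess import clean_window_mask
        x = rng.standard_normal(1000)
        _, grid = segment(x, 10.0, 10.0)  # W=100, S=50, K=19
        bad = np.zeros(1000, dtype=bool)
        bad[120:130] = True  # inside windows starting at 50 and 100
        keep = clean_window_mask(grid, bad)
        assert keep.sum() == grid.K - 2
        assert not keep[1] and not keep[2]
        with pytest.raises(ValueError):
            clean_window_mask(grid, bad[:-1])
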