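"""PLI, wPLI, AEC estimators: oracle equivalence, ranges, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from docfc.connectivity import (AnalyticSignal, aec, analytic,
                                connectivity_matrix, pair_index, pli,
                                unvectorize_upper, vectorize_upper, wpli)

FS = 256.0


def _tone(f, dur=4.0, amp=1.0, phase=0.0):
    t = np.arange(int(dur * FS)) / FS
    return amp * np.cos(2 * np.pi * f * t + phase)


def _from_phase(phases, env=None):
    """Analytic signal with prescribed phase series and envelope."""
    env = np.ones_like(phases) if env is None else env
    return AnalyticSignal(env * np.exp(1j * phases))


class TestAnalytic:
    def test_tone_envelope_matches_amplitude(self):
        a = analytic(_tone(10.0, amp=2.5))
        core = a.envelope[int(FS):-int(FS)]
        assert np.max(np.abs(core - 2.5) / 2.5) <= 0.02

    def test_envelope_dominates_signal(self, rng):
        x = rng.standard_normal(512)
        a = analytic(x)
        assert np.all(a.envelope >= np.abs(x) - 1e-9)

    def test_tone_phase_increment(self):
        f = 10.0
        a = analytic(_tone(f))
        dphi = np.angle(np.exp(1j * np.diff(a.phase[int(FS):-int(FS)])))
        np.testing.assert_allclose(dphi, 2 * np.pi * f / FS, rtol=0.02)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            analytic(np.ones(4))


class TestPLI:
    def test_identical_signals_give_zero(self):
        a = analytic(_tone(10.0))
        assert pli(a, a) == 0.0

    def test_constant_quarter_cycle_lag_gives_one(self):
        ph = 2 * np.pi * 10.0 * np.arange(1024) / FS
        assert pli(_from_phase(ph), _from_phase(ph - np.pi / 2)) == \
            pytest.approx(1.0)

    def test_asymmetric_two_point_lag_distribution(self, rng):
        # lags +pi/4 w.p. 0.75 and -pi/4 w.p. 0.25: brute-force expectation
        # of the sign sequence gives |0.75 - 0.25| = 0.5
        n = 40000
        lags = np.where(rng.random(n) < 0.75, np.pi / 4, -np.pi / 4)
        oracle = abs(np.sign(np.sin(lags)).sum() / n)
        base = rng.uniform(-np.pi, np.pi, n)
        got = pli(_from_phase(base), _from_phase(base - lags))
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(0.5, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pli(_from_phase(np.zeros(10)), _from_phase(np.zeros(11)))


class TestWPLI:
    def test_constant_lag_gives_one_any_envelope(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 2048)
        env = 1.0 + rng.random(2048)
        assert wpli(_from_phase(ph, env),
                    _from_phase(ph - np.pi / 2)) == pytest.approx(1.0)

    def test_zero_lag_identical_signals_give_zero(self):
        a = analytic(_tone(10.0))
        assert wpli(a, a) == 0.0

    def test_unit_envelope_reduces_to_sine_ratio(self, rng):
        # with A == 1 the estimator equals |E[sin d]| / E[|sin d|]
        for _ in range(100):
            d = rng.uniform(-np.pi, np.pi, 200)
            base = rng.uniform(-np.pi, np.pi, 200)
            got = wpli(_from_phase(base), _from_phase(base - d))
            oracle = abs(np.mean(np.sin(d))) / np.mean(np.abs(np.sin(d)))
            assert got == pytest.approx(oracle, abs=1e-12)


class TestAEC:
    def test_self_correlation_is_one(self):
        a = analytic(_tone(10.0) * (1.5 + _tone(0.5)))
        assert aec(a, a) == pytest.approx(1.0)

    def test_anticorrelated_envelopes(self, rng):
        t = np.arange(2048) / FS
        env = 2.0 + np.sin(2 * np.pi * 0.7 * t)
        x = _from_phase(2 * np.pi * 10 * t, env)
        y = _from_phase(rng.uniform(-np.pi, np.pi, 2048), 5.0 - env)
        assert aec(x, y) == pytest.approx(-1.0)

    def test_constant_envelope_returns_zero(self):
        t = np.arange(1024) / FS
        x = _from_phase(2 * np.pi * 10 * t)  # envelope identically 1
        y = _from_phase(2 * np.pi * 11 * t, 1.0 + 0.3 * np.sin(t))
        assert aec(x, y) == 0.0

    def test_phase_randomization_invariance(self, rng):
        # AEC depends only on envelopes: re-carrier one channel, same value
        t = np.arange(4096) / FS
        env_x = 2.0 + np.sin(2 * np.pi * 0.4 * t)
        env_y = 2.0 + np.cos(2 * np.pi * 0.3 * t)
        y = _from_phase(2 * np.pi * 9 * t, env_y)
        v1 = aec(_from_phase(2 * np.pi * 10 * t, env_x), y)
        v2 = aec(_from_phase(rng.uniform(-np.pi, np.pi, 4096), env_x), y)
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestConnectivityMatrix:
    def _window(self, rng, nch=19, n=512):
        return rng.standard_normal((nch, n))

    @pytest.mark.parametrize("metric", ["PLI", "wPLI", "AEC"])
    def test_shape_symmetry_and_diagonal(self, rng, metric):
        m = connectivity_matrix(self._window(rng), metric)
        assert m.values.shape == (19, 19)
        np.testing.assert_allclose(m.values, m.values.T)
        diag = 1.0 if metric == "AEC" else 0.0
        np.testing.assert_allclose(np.diag(m.values), diag)

    @pytest.mark.parametrize("metric", ["PLI", "wPLI", "AEC"])
    def test_channel_permutation_equivariance(self, rng, metric):
        w = self._window(rng, nch=6)
        perm = rng.permutation(6)
        m = connectivity_matrix(w, metric).values
        mp = connectivity_matrix(w[perm], metric).values
        np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], atol=1e-12)

    def test_duplicated_channels(self, rng):
        x = rng.standard_normal(512)
        w = np.vstack([x, x, rng.standard_normal(512)])
        assert connectivity_matrix(w, "AEC").values[0, 1] == \
            pytest.approx(1.0)
        assert connectivity_matrix(w, "PLI").values[0, 1] == 0.0

    def test_matches_naive_pairwise_loops(self, rng):
        """Vectorized all-pairs path equals the scalar estimators, 50 draws."""
        from scipy.signal import hilbert
        for _ in range(50):
            w = rng.standard_normal((4, 64))
            z = hilbert(w, axis=1)
            for metric, fn in [("PLI", pli), ("wPLI", wpli), ("AEC", aec)]:
                m = connectivity_matrix(w, metric).values
                for i in range(4):
                    for j in range(i + 1, 4):
                        want = fn(AnalyticSignal(z[i]), AnalyticSignal(z[j]))
                        assert m[i, j] == pytest.approx(want, abs=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ranges_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((3, 128)) * rng.uniform(0.1, 10)
        for metric, lo in [("PLI", 0.0), ("wPLI", 0.0), ("AEC", -1.0)]:
            v = connectivity_matrix(w, metric).values
            assert v.min() >= lo - 1e-12 and v.max() <= 1.0 + 1e-12

    @pytest.mark.parametrize("metric", ["PLI", "wPLI"])
    def test_amplitude_invariance_of_phase_metrics(self, rng, metric):
        w = rng.standard_normal((4, 256))
        scale = rng.uniform(0.5, 5.0, size=(4, 1))
        m1 = connectivity_matrix(w, metric).values
        m2 = connectivity_matrix(w * scale, metric).values
        np.testing.assert_allclose(m1, m2, atol=1e-10)

    def test_aec_common_rescaling_invariance(self, rng):
        w = rng.standard_normal((3, 256))
        m1 = connectivity_matrix(w, "AEC").values
        m2 = connectivity_matrix(w * 3.7, "AEC").values
        np.testing.assert_allclose(m1, m2, atol=1e-10)


class TestVectorization:
    @pytest.mark.parametrize("n,expected", [(19, 171), (3, 3), (4, 6)])
    def test_feature_length(self, rng, n, expected):
        m = connectivity_matrix(rng.standard_normal((n, 128)), "AEC")
        assert len(vectorize_upper(m)) == expected
        assert len(pair_index(n)) == expected

    def test_round_trip_preserves_off_diagonals(self, rng):
        m = connectivity_matrix(rng.standard_normal((5, 128)), "wPLI").values
        v = vectorize_upper(m)
        back = unvectorize_upper(v, 5)
        np.testing.assert_array_equal(back[np.triu_indices(5, 1)], v)
        np.testing.assert_allclose(back + np.diag(np.diag(m)), m)

    def test_row_major_order(self):
        m = np.arange(16).reshape(4, 4).astype(float)
        m = (m + m.T) / 2
        v = vectorize_upper(m)
        np.testing.assert_array_equal(
            v, [m[0, 1], m[0, 2], m[0, 3], m[1, 2], m[1, 3], m[2, 3]])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            vectorize_upper(np.zeros((3, 4)))
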