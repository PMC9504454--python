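import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctxpred as cp


class TestSegmentation:
    def test_chromosome_20_scale_segment_count(self):
        segs = cp.segment_chromosome(64_444_167, None)
        assert segs.n_segments == 64

    def test_below_one_segment(self):
        assert cp.segment_chromosome(999_999, None).n_segments == 0

    def test_ten_percent_boundary_is_inclusive(self):
        L, S = 2_000_000, 1_000_000
        disq = np.zeros(L, dtype=bool)
        disq[:100_000] = True          # segment 0: exactly 10.0% -> kept
        disq[S : S + 100_001] = True   # segment 1: just above 10% -> dropped
        segs = cp.segment_chromosome(L, disq, segment_length=S)
        assert segs.included.tolist() == [True, False]
        assert segs.quality_fraction[0] == pytest.approx(0.10)

    def test_accepts_position_mask(self):
        g = cp.GenomeSequence.from_string("g", "ACGT" * 300)
        mask = cp.build_position_mask(g, 2)
        segs = cp.segment_chromosome(len(g), mask, segment_length=100)
        assert segs.n_segments == 12
        assert segs.included[1:-1].all()


class TestGCIndicator:
    @pytest.mark.parametrize("bases,expected", [
        ("ACGT", [0, 1, 1, 0]),
        ("GGCC", [1, 1, 1, 1]),
    ])
    def test_definition(self, bases, expected):
        ind, flags = cp.gc_indicator(cp.GenomeSequence.from_string("g", bases))
        assert ind.tolist() == expected
        assert not flags.any()

    def test_n_emits_zero_and_is_flagged(self):
        ind, flags = cp.gc_indicator(cp.GenomeSequence.from_string("g", "ATNTA"))
        assert ind.tolist() == [0, 0, 0, 0, 0]
        assert flags.tolist() == [False, False, True, False, False]


class TestFourier:
    def test_constant_array_is_dc_only(self):
        mags = cp.fourier_magnitudes(np.full(1000, 3.0))
        assert mags[0] == pytest.approx(3000.0)
        assert np.abs(mags[1:]).max() < 1e-8

    def test_pure_cosine_closed_form(self):
        L, f = 1_000_000, 5000
        values = np.cos(2 * np.pi * f * np.arange(L) / L)
        mags = cp.fourier_magnitudes(values)
        assert mags[f] == pytest.approx(L / 2, rel=1e-9)
        other = np.delete(mags, f)
        assert other.max() < 1e-4

    def test_matches_quadratic_dft_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random(64)
        mags = cp.fourier_magnitudes(x)
        n = np.arange(64)
        for f in range(33):  # direct O(L^2) DFT
            coef = np.sum(x * np.exp(-2j * np.pi * f * n / 64))
            assert mags[f] == pytest.approx(abs(coef), abs=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cp.fourier_magnitudes(np.array([1.0, np.nan, 2.0]))

    def test_parseval(self):
        rng = np.random.default_rng(1)
        x = rng.random(1000)
        mags = cp.fourier_magnitudes(x)
        # one-sided sum with double-count correction for interior frequencies
        total = mags[0] ** 2 + mags[-1] ** 2 + 2 * np.sum(mags[1:-1] ** 2)
        assert total == pytest.approx(1000 * np.sum(x ** 2), rel=1e-10)


class TestWindowedNorm:
    def test_single_coefficient_spectrum(self):
        L, f = 100_000, 5000
        values = np.cos(2 * np.pi * f * np.arange(L) / L)
        ws = cp.windowed_norm_spectrum(cp.fourier_magnitudes(values),
                                       window=1000, step=100)
        covers = (ws.start_frequencies <= f) & (f < ws.start_frequencies + 1000)
        assert ws.norms[covers] == pytest.approx(L / 2, rel=1e-6)
        assert np.abs(ws.norms[~covers]).max() < 1e-3

    def test_zero_input_and_euclidean_arithmetic(self):
        assert (cp.windowed_norm_spectrum(np.zeros(5000)).norms == 0).all()
        mags = np.zeros(2001)
        mags[10] = mags[20] = 7.0
        ws = cp.windowed_norm_spectrum(mags, window=1000, step=100)
        assert ws.norms[0] == pytest.approx(7.0 * np.sqrt(2))

    def test_dc_never_included(self):
        mags = np.zeros(2001)
        mags[0] = 1e9
        ws = cp.windowed_norm_spectrum(mags, window=1000, step=100)
        assert ws.norms.max() == 0.0
        assert ws.start_frequencies[0] == 1

    def test_squared_flag_gives_summed_power(self):
        rng = np.random.default_rng(0)
        mags = rng.random(3000)
        ws = cp.windowed_norm_spectrum(mags, window=500, step=100)
        wp = cp.windowed_norm_spectrum(mags, window=500, step=100, squared=True)
        np.testing.assert_allclose(ws.norms ** 2, wp.norms, rtol=1e-12)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=10)
    def test_invariant_under_sign_flip_and_constant_shift(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(2000)
        base = cp.windowed_norm_spectrum(cp.fourier_magnitudes(x), 100, 50).norms
        flipped = cp.windowed_norm_spectrum(cp.fourier_magnitudes(-x), 100, 50).norms
        shifted = cp.windowed_norm_spectrum(cp.fourier_magnitudes(x + 5.0), 100, 50).norms
        np.testing.assert_allclose(base, flipped, rtol=1e-9)
        np.testing.assert_allclose(base, shifted, rtol=1e-6, atol=1e-6)


class TestPeriodConversion:
    def test_nucleosome_scale_windows(self):
        pw = cp.frequency_window_to_periods(4000, 1000, 1_000_000)
        assert (pw.period_low, pw.period_high, pw.period_mid) == (200, 250, 222)

    @pytest.mark.parametrize("f_start,mid", [(7500, 125), (11_000, 87)])
    def test_mid_periods(self, f_start, mid):
        assert cp.frequency_window_to_periods(f_start, 1000, 1_000_000).period_mid == mid

    def test_zero_width_is_exact_ratio(self):
        pw = cp.frequency_window_to_periods(100, 0, 1000)
        assert pw.period_low == pw.period_high == pw.period_mid == 10

    def test_dc_rejected(self):
        with pytest.raises(ValueError):
            cp.frequency_window_to_periods(0, 1000, 1_000_000)


class TestControls:
    def _cosine(self, L=1_000_000, period=200):
        return np.cos(2 * np.pi * np.arange(L) / period)

    def test_shuffle_preserves_multiset_and_seed(self):
        x = np.arange(100, dtype=float)
        s1 = cp.shuffle_control(x, seed=5)
        s2 = cp.shuffle_control(x, seed=5)
        np.testing.assert_array_equal(np.sort(s1), x)
        np.testing.assert_array_equal(s1, s2)

    def test_shuffle_abolishes_planted_peak(self):
        x = self._cosine()
        peak = cp.peak_window(cp.windowed_norm_spectrum(
            cp.fourier_magnitudes(x), 1000, 100))[1]
        shuffled_peaks = [
            cp.peak_window(cp.windowed_norm_spectrum(
                cp.fourier_magnitudes(cp.shuffle_control(x, seed=s)), 1000, 100))[1]
            for s in range(10)
        ]
        assert np.mean(shuffled_peaks) < 0.05 * peak

    def test_randomize_empty_subset_is_identity(self):
        x = self._cosine(1000)
        np.testing.assert_array_equal(cp.randomize_control(x, np.array([], int), 0), x)

    def test_randomize_all_positions_is_input_independent(self):
        pos = np.arange(1000)
        a = cp.randomize_control(np.zeros(1000), pos, seed=9)
        b = cp.randomize_control(np.ones(1000), pos, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_half_randomization_retains_peak(self):
        x = self._cosine()
        L = x.size
        f = L // 200
        def peak_at_f(values):
            ws = cp.windowed_norm_spectrum(cp.fourier_magnitudes(values), 1000, 100)
            covers = (ws.start_frequencies <= f) & (f < ws.start_frequencies + 1000)
            return ws.norms[covers].max()
        peak = peak_at_f(x)
        retained = []
        for s in range(10):
            rng = np.random.default_rng(s)
            pos = rng.choice(L, size=L // 2, replace=False)
            retained.append(peak_at_f(cp.randomize_control(x, pos, seed=100 + s)))
        # half the coherent amplitude survives: expect ~50%, require >= 25%
        assert np.mean(retained) >= 0.25 * peak


class TestPlantedPeriodRecovery:
    def test_gc_array_peak_and_refprob_inheritance(self, planted_1mb):
        genome, _, spec = planted_1mb
        L = spec.length
        f_planted = L // spec.gc_period  # 5000 cycles per Mb
        ind, _ = cp.gc_indicator(genome)
        ws = cp.windowed_norm_spectrum(cp.fourier_magnitudes(ind), 1000, 100)
        f0, _ = cp.peak_window(ws)
        assert f0 <= f_planted < f0 + 1000
        res = cp.CentralModel(genome, k=3).fit()
        arr = cp.reference_base_probabilities(res, genome)
        ws2 = cp.windowed_norm_spectrum(cp.fourier_magnitudes(arr.values), 1000, 100)
        f0b, _ = cp.peak_window(ws2)
        assert f0b <= f_planted < f0b + 1000
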