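import numpy as np
import pytest

from caosc import (
    RawTrace,
    amplitude_spectrum,
    band_fractions,
    compute_f0,
    simulate_view,
    to_dff,
    view_synchrony,
)

from _oracles import rank_then_pearson


class TestViewSynchrony:
    def test_identical_traces_fully_synchronous(self, make_dff):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        res = view_synchrony([make_dff(x), make_dff(x.copy())])
        assert res.mean_coefficient == pytest.approx(1.0)

    def test_negated_trace_anticorrelated(self, make_dff):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        res = view_synchrony([make_dff(x), make_dff(-x)])
        assert res.mean_coefficient == pytest.approx(-1.0)

    def test_independent_noise_near_zero_and_matches_oracle(self, make_dff):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (10, 1000))
        res = view_synchrony([make_dff(row) for row in data])
        # 45 pairs, each with SD ~ 1/sqrt(n-1)
        assert abs(res.mean_coefficient) < 3 * (1 / np.sqrt(999)) / np.sqrt(45) * 3
        for i in range(10):
            for j in range(i + 1, 10):
                assert res.pair_matrix[i, j] == pytest.approx(
                    rank_then_pearson(data[i], data[j]), abs=1e-12
                )

    def test_matrix_is_symmetric_with_unit_diagonal(self, make_dff):
        rng = np.random.default_rng(4)
        res = view_synchrony([make_dff(rng.normal(0, 1, 50)) for _ in range(4)])
        np.testing.assert_allclose(res.pair_matrix, res.pair_matrix.T)
        np.testing.assert_allclose(np.diag(res.pair_matrix), 1.0)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3, lambda v: 2 * v + 5])
    def test_invariant_under_monotone_transforms(self, make_dff, transform):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 300), rng.normal(0, 1, 300)
        plain = view_synchrony([make_dff(a), make_dff(b)]).mean_coefficient
        warped = view_synchrony([make_dff(transform(a)), make_dff(b)]).mean_coefficient
        assert warped == pytest.approx(plain, abs=1e-12)

    def test_constant_trace_excluded_with_warning(self, make_dff):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        with pytest.warns(RuntimeWarning):
            res = view_synchrony([make_dff(a), make_dff(b), make_dff(np.zeros(100))])
        expected = view_synchrony([make_dff(a), make_dff(b)]).mean_coefficient
        assert res.mean_coefficient == pytest.approx(expected)

    def test_requires_two_equal_length_traces(self, make_dff):
        with pytest.raises(ValueError):
            view_synchrony([make_dff(np.zeros(50))])
        with pytest.raises(ValueError):
            view_synchrony([make_dff(np.zeros(50)), make_dff(np.zeros(51))])

    def test_monotone_in_network_shared_fraction(self, stage_presets):
        import dataclasses

        base = stage_presets[("DIV28", "healthy")]
        levels = []
        for shared in (0.0, 0.5, 1.0):
            p = dataclasses.replace(base, shared_fraction=shared)
            view = simulate_view(p, 10, 600, 5.0, seed=3)
            dffs = []
            for c in range(10):
                f0 = compute_f0(RawTrace(view.traces[c] - p.background_F, 5.0))
                dffs.append(to_dff(RawTrace(view.traces[c], 5.0), p.background_F, f0))
            levels.append(view_synchrony(dffs).mean_coefficient)
        assert levels[0] < levels[1] < levels[2]

    def test_fully_shared_noise_free_view_is_unity(self, stage_presets):
        import dataclasses

        p = dataclasses.replace(
            stage_presets[("DIV28", "healthy")], shared_fraction=1.0, noise_sd=0.0
        )
        view = simulate_view(p, 5, 600, 5.0, seed=4)
        dffs = []
        for c in range(5):
            f0 = compute_f0(RawTrace(view.traces[c] - p.background_F, 5.0))
            dffs.append(to_dff(RawTrace(view.traces[c], 5.0), p.background_F, f0))
        assert view_synchrony(dffs).mean_coefficient == pytest.approx(1.0)


class TestAmplitudeSpectrum:
    def test_pure_tone_amplitude_is_recovered(self, make_dff):
        fs, n, f_tone, amp = 5.0, 3000, 0.050, 2.0
        t = np.arange(n) / fs
        dff = make_dff(amp * np.sin(2 * np.pi * f_tone * t), fs=fs)
        spec = amplitude_spectrum(dff)
        k = int(round(f_tone * n / fs))
        assert spec.freqs[k] == pytest.approx(f_tone)
        assert spec.amplitude[k] == pytest.approx(amp, rel=1e-9)
        others = np.delete(spec.amplitude, k)
        assert np.max(others) < 1e-9

    def test_constant_trace_has_empty_spectrum(self, make_dff):
        spec = amplitude_spectrum(make_dff(np.full(64, 3.0)))
        np.testing.assert_allclose(spec.amplitude, 0.0, atol=1e-12)

    def test_parseval_identity_on_noise(self, make_dff):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 4096)
        spec = amplitude_spectrum(make_dff(x))
        power = np.sum(spec.amplitude[1:-1] ** 2) / 2 + spec.amplitude[-1] ** 2
        assert power == pytest.approx(np.var(x), rel=0.01)

    def test_scale_equivariance(self, make_dff):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 512)
        a1 = amplitude_spectrum(make_dff(x)).amplitude
        a2 = amplitude_spectrum(make_dff(3.5 * x)).amplitude
        np.testing.assert_allclose(a2, 3.5 * a1, rtol=1e-9, atol=1e-12)

    def test_short_trace_rejected(self, make_dff):
        with pytest.raises(ValueError):
            amplitude_spectrum(make_dff(np.zeros(15)))


class TestBandFractions:
    def test_single_slow_tone(self, make_dff):
        t = np.arange(3000) / 5.0
        spec = amplitude_spectrum(make_dff(np.sin(2 * np.pi * 0.05 * t), fs=5.0))
        ultra, slow, fast = band_fractions(spec)
        assert ultra == pytest.approx(0.0, abs=0.5)
        assert slow == pytest.approx(100.0, abs=0.5)
        assert fast == pytest.approx(0.0, abs=0.5)

    def test_equal_tones_split_evenly(self, make_dff):
        t = np.arange(6000) / 5.0
        x = np.sin(2 * np.pi * 0.005 * t) + np.sin(2 * np.pi * 0.050 * t)
        ultra, slow, fast = band_fractions(amplitude_spectrum(make_dff(x, fs=5.0)))
        assert ultra == pytest.approx(50.0, abs=1.0)
        assert slow == pytest.approx(50.0, abs=1.0)
        assert fast == pytest.approx(0.0, abs=0.5)

    def test_fractions_sum_to_hundred(self, make_dff):
        rng = np.random.default_rng(9)
        fr = band_fractions(amplitude_spectrum(make_dff(rng.normal(0, 1, 2048))))
        assert sum(fr) == pytest.approx(100.0, abs=1e-9)

    def test_low_nyquist_flags_fast_band(self, make_dff):
        rng = np.random.default_rng(10)
        dff = make_dff(rng.normal(0, 1, 200), fs=0.4)  # Nyquist 0.2 Hz < 300 mHz
        with pytest.warns(RuntimeWarning):
            ultra, slow, fast = band_fractions(amplitude_spectrum(dff))
        assert np.isnan(fast)

    def test_band_composition_shifts_with_maturation(self, stage_presets):
        # kernels slow with age: the fast-band share shrinks from the first
        # week to DIV 28 while the slow band always exceeds the ultra-slow
        def mean_fractions(day):
            p = stage_presets[(f"DIV{day}", "healthy")]
            view = simulate_view(p, 5, 600, 5.0, seed=6)
            out = []
            for c in range(5):
                f0 = compute_f0(RawTrace(view.traces[c] - p.background_F, 5.0))
                dff = to_dff(RawTrace(view.traces[c], 5.0), p.background_F, f0)
                out.append(band_fractions(amplitude_spectrum(dff)))
            return np.mean(out, axis=0)

        early, mid, late = mean_fractions(3), mean_fractions(17), mean_fractions(28)
        assert mid[1] > mid[0]  # slow exceeds ultra-slow at DIV 17
        assert late[2] < mid[2] < early[2]  # fast share declines with age
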