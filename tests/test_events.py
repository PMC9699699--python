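import dataclasses

import numpy as np
import pytest

from caosc import (
    RawTrace,
    compute_f0,
    detect_events,
    event_frequency_mHz,
    event_kernel,
    kernel_fwhm,
    simulate_trials,
    simulate_view,
    to_dff,
    trial_success_rate,
    waveform_metrics,
)
from caosc.events import EventTable, _empty_event_frame

from _oracles import brute_force_detect, halfwidth_by_dense_grid


class TestDetectEvents:
    def test_single_rectangular_pulse(self, make_dff):
        x = np.zeros(100)
        x[40:60] = 1.0
        table = detect_events(make_dff(x))
        assert len(table) == 1
        assert table.events["amplitude"].iloc[0] == pytest.approx(1.0)

    def test_everything_below_threshold(self, make_dff):
        # bounded uniform ripple: its robust 3 SD sits above the extremes
        rng = np.random.default_rng(0)
        x = rng.uniform(-0.01, 0.01, 200)
        assert len(detect_events(make_dff(x))) == 0

    def test_zero_variance_trace_warns(self, make_dff):
        with pytest.warns(RuntimeWarning):
            table = detect_events(make_dff(np.full(50, 2.0)))
        assert len(table) == 0

    def test_threshold_recorded(self, make_dff):
        rng = np.random.default_rng(0)
        table = detect_events(make_dff(rng.normal(0, 0.01, 500)))
        assert np.isfinite(table.threshold_used)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_scan_on_noise(self, make_dff, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.02, 1500)
        # sprinkle a few transients so both detectors face real structure
        t_grid = np.arange(1500) / 5.0
        for t_e, a in ((30.0, 0.3), (100.0, 0.15), (101.0, 0.4), (220.0, 0.6)):
            x += a * event_kernel(t_grid - t_e, 0.1, 0.5)
        table = detect_events(make_dff(x, fs=5.0))
        oracle = brute_force_detect(x, fs=5.0)
        assert table.events["peak_index"].tolist() == oracle


class TestEventFrequency:
    def test_twelve_events_in_ten_minutes(self):
        frame = _empty_event_frame()
        frame = frame.reindex(range(12)).assign(
            peak_index=np.arange(12) * 10,
            t_peak=np.linspace(10, 590, 12),
            amplitude=1.0,
        )
        table = EventTable(
            events=frame, duration_s=600.0, cell_id=None, threshold_used=0.1
        )
        assert event_frequency_mHz(table) == pytest.approx(20.0)

    def test_no_events_is_zero(self):
        table = EventTable(
            events=_empty_event_frame(), duration_s=600.0, cell_id=None,
            threshold_used=0.1,
        )
        assert event_frequency_mHz(table) == 0.0

    def test_first_week_frequency_recovered_from_truth(self, stage_presets):
        # detection-independent check: the generator's truth lists alone
        # reproduce the 150 mHz first-week rate
        p = stage_presets[("DIV3", "healthy")]
        view = simulate_view(p, 30, 600, 5.0, seed=1)
        mean_mHz = np.mean(
            [1000.0 * len(t) / 600.0 for t, _ in view.truth_events]
        )
        se = 1000.0 * np.sqrt(
            p.event_rate * (p.shared_fraction + (1 - p.shared_fraction) / 30) / 600.0
        )
        assert abs(mean_mHz - 150.0) <= 3 * se


class TestWaveformMetrics:
    def test_triangular_pulse_half_base(self, make_dff):
        # symmetric triangle with a 4 s base: FWHM is half the base
        fs = 100.0
        t = np.arange(0, 30, 1 / fs)
        x = np.clip(1.0 - np.abs(t - 15.0) / 2.0, 0.0, None)
        dff = make_dff(x, fs=fs)
        table = waveform_metrics(dff, detect_events(dff))
        assert len(table) == 1
        row = table.events.iloc[0]
        assert row["fwhm"] == pytest.approx(2.0, abs=2 / fs)
        assert row["t_on50"] == pytest.approx(1.0, abs=2 / fs)
        assert row["t_off50"] == pytest.approx(1.0, abs=2 / fs)

    def test_instant_rise_exponential_decay(self, make_dff):
        fs, tau = 100.0, 1.5
        t = np.arange(0, 30, 1 / fs)
        x = np.where(t >= 10.0, np.exp(-(t - 10.0) / tau), 0.0)
        dff = make_dff(x, fs=fs)
        table = waveform_metrics(dff, detect_events(dff))
        assert table.events["t_off50"].iloc[0] == pytest.approx(
            tau * np.log(2), abs=2 / fs
        )

    def test_generator_kernel_width_matches_root_solved_oracle(
        self, make_dff, stage_presets
    ):
        p = stage_presets[("DIV28", "healthy")]
        fs = 5.0
        t_grid = np.arange(0, 120, 1 / fs)
        x = 1.0 * event_kernel(t_grid - 40.0, p.rise_tau, p.decay_tau, p.plateau_s)
        dff = make_dff(x, fs=fs)
        table = waveform_metrics(dff, detect_events(dff))
        oracle = halfwidth_by_dense_grid(
            lambda tt: event_kernel(tt, p.rise_tau, p.decay_tau, p.plateau_s),
            t_max=60.0,
        )
        assert table.events["fwhm"].iloc[0] == pytest.approx(oracle, abs=1 / fs)

    @pytest.mark.parametrize("shift,scale", [(0.0, 1.0), (0.5, 1.0), (0.0, 7.0), (-0.2, 0.3)])
    def test_fwhm_invariant_to_offset_and_scale(self, make_dff, shift, scale):
        fs = 20.0
        t_grid = np.arange(0, 60, 1 / fs)
        base = event_kernel(t_grid - 20.0, 0.3, 1.5)
        ref = waveform_metrics(
            make_dff(base, fs=fs), detect_events(make_dff(base, fs=fs))
        ).events["fwhm"].iloc[0]
        x = shift + scale * base
        dff = make_dff(x, fs=fs)
        got = waveform_metrics(dff, detect_events(dff)).events["fwhm"].iloc[0]
        assert got == pytest.approx(ref, abs=1e-9)

    def test_truncated_event_flagged_missing(self, make_dff):
        fs = 5.0
        t_grid = np.arange(0, 60, 1 / fs)
        x = event_kernel(t_grid - 58.0, 0.3, 3.0)  # decay cut by the trace end
        dff = make_dff(x, fs=fs)
        table = waveform_metrics(dff, detect_events(dff))
        assert len(table) == 1
        assert np.isnan(table.events["fwhm"].iloc[0])

    def test_overlapping_events_split_at_minimum(self, make_dff):
        fs = 50.0
        rng = np.random.default_rng(0)
        t_grid = np.arange(0, 40, 1 / fs)
        x = (
            event_kernel(t_grid - 10.0, 0.1, 0.8)
            + event_kernel(t_grid - 14.0, 0.1, 0.8)
            + rng.normal(0, 0.01, t_grid.size)
        )
        dff = make_dff(x, fs=fs)
        table = waveform_metrics(dff, detect_events(dff))
        big = table.events[table.events["amplitude"] > 0.3]
        assert len(big) == 2  # the merged excursion was split into both transients
        np.testing.assert_allclose(big["t_peak"], [10.2, 14.2], atol=0.3)
        assert big["fwhm"].notna().all()


class TestTrialSuccessRate:
    def test_noise_free_injections_always_succeed(self, stage_presets):
        p = dataclasses.replace(stage_presets[("DIV14", "healthy")], noise_sd=0.0)
        ts = simulate_trials(p, 12, 1.0, 1.0, fs=5.0, seed=2)
        assert trial_success_rate(ts) == 1.0

    def test_noise_free_blanks_never_succeed(self, stage_presets):
        p = dataclasses.replace(stage_presets[("DIV14", "healthy")], noise_sd=0.0)
        ts = simulate_trials(p, 12, 0.0, 1.0, fs=5.0, seed=2)
        assert trial_success_rate(ts) == 0.0

    def test_rate_matches_binomial_oracle(self, stage_presets):
        p = stage_presets[("DIV14", "healthy")]
        ts = simulate_trials(p, 1000, 0.7, 2.0, fs=5.0, seed=2)
        rate = trial_success_rate(ts)
        assert abs(rate - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / 1000)


def test_full_chain_frequency_on_plateau_stage(stage_presets):
    # extraction + detection on the mature stage: plateau around 20 mHz
    p = stage_presets[("DIV28", "healthy")]
    view = simulate_view(p, 30, 600, 5.0, seed=1)
    freqs = []
    for c in range(30):
        raw = RawTrace(view.traces[c], 5.0)
        f0 = compute_f0(RawTrace(raw.values - p.background_F, 5.0))
        dff = to_dff(raw, p.background_F, f0)
        freqs.append(event_frequency_mHz(detect_events(dff)))
    se = 1000.0 * np.sqrt(
        p.event_rate * (p.shared_fraction + (1 - p.shared_fraction) / 30) / 600.0
    )
    assert abs(np.mean(freqs) - 20.0) <= 3 * se
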