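"""Generator: presets, duration model moments, signal structure, arrays."""

import numpy as np
import pytest
from scipy.signal import welch

from slowosc import synth


class TestPresets:
    def test_duration_matched_uses_printed_pooled_means(self):
        p = synth.preset("SAMP8_5M", "duration_matched")
        assert p.mean_down_s == pytest.approx(1.1)
        assert p.mean_up_s == pytest.approx(0.61)
        assert p.cycle_cv == pytest.approx(0.53)

    def test_control_duration_matched(self):
        p = synth.preset("SAMR1_5M", "duration_matched")
        assert p.mean_down_s == pytest.approx(0.71)
        assert p.mean_up_s == pytest.approx(0.49)
        assert p.cycle_cv == pytest.approx(0.40)

    @pytest.mark.parametrize(
        "name,freq",
        [("SAMR1_5M", 1.02), ("SAMP8_5M", 0.72), ("SAMR1_7M", 0.91), ("SAMP8_7M", 0.77)],
    )
    def test_frequency_matched_expected_mean_cycle_frequency(self, name, freq):
        p = synth.preset(name, "frequency_matched")
        assert p.expected_so_freq_hz == pytest.approx(freq, rel=1e-3)

    def test_up_down_ratio_preserved(self):
        p = synth.preset("SAMP8_5M", "frequency_matched")
        assert p.mean_up_s / p.mean_cycle_s == pytest.approx(0.61 / 1.71, rel=1e-6)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            synth.preset("SAMP9_5M")


class TestDurationModel:
    def test_zero_cv_gives_constant_cycles(self):
        p = synth.GeneratorParams(mean_up_s=0.5, mean_down_s=0.7, cycle_cv=0.0)
        up, down = synth.sample_state_durations(p, 50)
        np.testing.assert_allclose(up, 0.5)
        np.testing.assert_allclose(down, 0.7)

    def test_sample_mean_matches_parameter(self):
        p = synth.preset("SAMP8_5M", "duration_matched", seed=5)
        n = 10000
        up, down = synth.sample_state_durations(p, n)
        se = down.std(ddof=1) / np.sqrt(n)
        assert abs(down.mean() - 1.1) < 3 * se
        se_up = up.std(ddof=1) / np.sqrt(n)
        assert abs(up.mean() - 0.61) < 3 * se_up

    def test_seed_determinism(self):
        p = synth.preset("SAMR1_5M", seed=9)
        a = synth.sample_state_durations(p, 100)
        b = synth.sample_state_durations(p, 100)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_cycle_cv_realized_over_many_cycles(self):
        """Empirical per-cycle frequency CV within 5% of the target."""
        for name in ("SAMR1_5M", "SAMP8_7M"):
            p = synth.preset(name, seed=2)
            up, down = synth.sample_state_durations(p, 6000)
            f = 1.0 / (up + down)
            cv = f.std(ddof=1) / f.mean()
            assert cv == pytest.approx(p.cycle_cv, rel=0.05)

    def test_durations_respect_floor(self):
        p = synth.preset("SAMP8_7M", seed=0)
        up, down = synth.sample_state_durations(p, 5000)
        assert up.min() >= p.state_floor_s
        assert down.min() >= p.state_floor_s

    def test_infeasible_cv_raises(self):
        p = synth.GeneratorParams(mean_up_s=0.2, mean_down_s=0.2, cycle_cv=0.9)
        with pytest.raises(ValueError, match="infeasible"):
            synth.sample_state_durations(p, 10)


class TestChannelSynthesis:
    def test_recording_determinism(self):
        p = synth.GeneratorParams(rate=5000.0, seed=4)
        r1, t1 = synth.synthesize_channel(p, 20.0)
        r2, t2 = synth.synthesize_channel(p, 20.0)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        np.testing.assert_array_equal(t1.cycle_table, t2.cycle_table)

    def test_duration_too_short_rejected(self):
        p = synth.GeneratorParams()
        with pytest.raises(ValueError, match="too short"):
            synth.synthesize_channel(p, 5.0)

    def test_mua_band_power_higher_in_true_up(self):
        """Welch on truth-labeled samples: 200-1500 Hz power Up > Down."""
        p = synth.GeneratorParams(rate=5000.0, seed=7, slow_amp=0.0, gamma_amp=0.0)
        rec, truth = synth.synthesize_channel(p, 30.0)
        x = rec.channel(0)
        up, down = x[truth.state_labels], x[~truth.state_labels]
        for seg_up, seg_down in [(up, down)]:
            f, p_up = welch(seg_up, fs=rec.rate, nperseg=1024)
            _, p_down = welch(seg_down, fs=rec.rate, nperseg=1024)
            band = (f >= 200) & (f <= 1500)
            assert p_up[band].mean() > p_down[band].mean()

    def test_logmua_up_exceeds_down_on_truth_labels(self, small_recording):
        from slowosc.mua import estimate_logmua

        (rec, truth), params = small_recording
        assert params.up_rate_hz > params.down_rate_hz
        lm = estimate_logmua(rec)
        w = int(round(0.005 * rec.rate))
        labels = truth.state_labels[: len(lm) * w].reshape(-1, w).mean(axis=1) > 0.5
        assert lm.values[labels].mean() > lm.values[~labels].mean()

    def test_null_model_is_stationary(self):
        """Equal rates and no slow/gamma drive leave no state signature."""
        p = synth.GeneratorParams(
            rate=5000.0, seed=3, slow_amp=0.0, gamma_amp=0.0,
            up_rate_hz=500.0, down_rate_hz=500.0,
        )
        rec, truth = synth.synthesize_channel(p, 30.0)
        x = rec.channel(0)
        # 1/f background is long-range correlated, so segment variances
        # fluctuate; only demand the absence of a systematic state signature
        v_up = x[truth.state_labels].var()
        v_down = x[~truth.state_labels].var()
        assert v_up == pytest.approx(v_down, rel=0.1)


class TestArraySynthesis:
    def test_first_to_last_lag_is_span_over_speed(self):
        p = synth.GeneratorParams(rate=5000.0, seed=0)
        arr = synth.ArrayParams(speed_mm_s=15.0, onset_jitter_s=0.0)
        rec, truth = synth.synthesize_array(p, arr, 20.0)
        lag = truth.channel_onsets[:, -1] - truth.channel_onsets[:, 0]
        np.testing.assert_allclose(lag, 1.5 / 15.0)

    def test_zero_jitter_lags_linear_in_position(self):
        p = synth.GeneratorParams(rate=5000.0, seed=1)
        arr = synth.ArrayParams(speed_mm_s=20.0, onset_jitter_s=0.0)
        _, truth = synth.synthesize_array(p, arr, 20.0)
        lags = truth.true_lags
        pos = arr.positions_mm
        for w in range(lags.shape[0]):
            slope = np.polyfit(pos, lags[w], 1)[0]
            assert slope == pytest.approx(1.0 / 20.0, rel=1e-9)

    def test_origin_last_channel_reverses_direction(self):
        p = synth.GeneratorParams(rate=5000.0, seed=1)
        arr = synth.ArrayParams(speed_mm_s=20.0, onset_jitter_s=0.0, origin="last_channel")
        _, truth = synth.synthesize_array(p, arr, 20.0)
        assert truth.channel_onsets[0, 0] > truth.channel_onsets[0, -1]

    def test_invalid_speed(self):
        with pytest.raises(ValueError):
            synth.ArrayParams(speed_mm_s=0.0)
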