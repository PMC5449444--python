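"""Fingerprint features, PCA combination, thresholding, SO metrics."""

import numpy as np
import pytest
from scipy.signal import periodogram, square

from slowosc import detection
from slowosc.io import Recording

from conftest import label_agreement

RATE = 5000.0


def _rec(x, rate=RATE):
    return Recording(samples=np.asarray(x, dtype=np.float32)[None, :], rate=rate)


class TestSOEnvelope:
    def test_zero_signal_gives_zero(self):
        env = detection.so_envelope(_rec(np.zeros(int(10 * RATE))))
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_square_wave_tracked_fast_content_removed(self):
        t = np.arange(int(20 * RATE)) / RATE
        x = square(2 * np.pi * 0.5 * t) + 0.5 * np.sin(2 * np.pi * 40 * t)
        env = detection.so_envelope(_rec(x))
        f, p = periodogram(env, fs=1 / 0.005)
        p_slow = p[(f > 0.2) & (f < 1.5)].sum()
        p_fast = p[(f > 35) & (f < 45)].sum()
        assert p_slow > 100 * p_fast
        # tracks the 0.5 Hz alternation
        assert np.corrcoef(env, square(2 * np.pi * 0.5 * (np.arange(env.size) * 0.005)))[
            0, 1
        ] ** 2 > 0.5

    def test_oriented_up_positive_on_generator_truth(self, small_recording):
        """Up deflections are negative in the raw signal but positive here."""
        (rec, truth), _ = small_recording
        env = detection.so_envelope(rec)
        w = int(round(0.005 * rec.rate))
        labels = truth.state_labels[: env.size * w].reshape(-1, w).mean(axis=1) > 0.5
        assert env[labels].mean() > env[~labels].mean()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            detection.so_envelope(_rec(np.zeros(int(11 * RATE))), cutoff_hz=3000.0)


class TestGammaVarianceEnvelope:
    def test_zero_signal(self):
        out = detection.gamma_variance_envelope(_rec(np.zeros(int(10 * RATE))))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_tone_in_band_plateau_is_half_amplitude_squared(self):
        """A 40 Hz tone of amplitude a on [1,2] s: variance plateau ~ a^2/2."""
        a = 3.0
        t = np.arange(int(4 * RATE)) / RATE
        x = np.where((t >= 1) & (t < 2), a * np.sin(2 * np.pi * 40 * t), 0.0)
        out = detection.gamma_variance_envelope(_rec(x))
        tb = np.arange(out.size) * 0.005
        inside = out[(tb > 1.2) & (tb < 1.8)]
        outside = out[(tb > 2.5) | (tb < 0.7)]
        assert inside.mean() == pytest.approx(a**2 / 2, rel=0.05)
        assert outside.mean() < 0.01 * inside.mean()

    def test_out_of_band_tone_rejected(self):
        t = np.arange(int(4 * RATE)) / RATE
        x = np.sin(2 * np.pi * 500 * t)
        out = detection.gamma_variance_envelope(_rec(x))
        assert out.mean() < 1e-3  # 500 Hz is far outside 20-80 Hz


class TestCombineFeaturesPCA:
    def test_identical_series_symmetric_weights(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=2000)
        fs = detection.combine_features_pca(s, s, s)
        np.testing.assert_allclose(np.abs(fs.pca_weights), 1 / np.sqrt(3), atol=1e-9)
        # combined proportional to the series
        c = np.corrcoef(fs.combined, s)[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_gets_smallest_weight(self):
        """Two state-modulated series + one independent noise series.

        Oracle: the analytic correlation matrix [[1, rho, 0], [rho, 1, 0],
        [0, 0, 1]] has first eigenvector (1, 1, 0)/sqrt(2) for rho > 0, so
        the noise loading must come out smallest.
        """
        rng = np.random.default_rng(1)
        state = np.repeat(rng.integers(0, 2, 40), 100).astype(float)
        s1 = state + 0.3 * rng.normal(size=state.size)
        s2 = 0.8 * state + 0.3 * rng.normal(size=state.size)
        s3 = rng.normal(size=state.size)
        fs = detection.combine_features_pca(s1, s2, s3)
        w = np.abs(fs.pca_weights)
        assert w[2] < w[0] and w[2] < w[1]

    def test_combined_variance_equals_first_eigenvalue(self):
        rng = np.random.default_rng(2)
        s1, s2, s3 = rng.normal(size=(3, 3000))
        s2 += 0.5 * s1
        fs = detection.combine_features_pca(s1, s2, s3)
        Z = np.vstack(
            [(s - s.mean()) / s.std() for s in (s1, s2, s3)]
        )
        eig = np.linalg.eigvalsh(Z @ Z.T / Z.shape[1]).max()
        assert fs.combined.var() == pytest.approx(eig, rel=1e-9)

    def test_constant_feature_weight_zero_with_warning(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=1000)
        with pytest.warns(UserWarning, match="constant"):
            fs = detection.combine_features_pca(np.ones(1000), s, s + 0.1 * rng.normal(size=1000))
        assert fs.pca_weights[0] == 0.0


class TestSegmentStates:
    def _square_fs(self, high=1.0, low=-1.0, period_bins=200, n_periods=20):
        x = np.tile(
            np.concatenate([np.full(period_bins // 2, low), np.full(period_bins // 2, high)]),
            n_periods,
        ).astype(float)
        x += 0.01 * np.random.default_rng(0).normal(size=x.size)
        return detection.FeatureSet(x, x, x, combined=x, pca_weights=np.ones(3) / np.sqrt(3))

    def test_square_wave_boundaries_at_transitions(self):
        fs = self._square_fs()
        seg = detection.segment_states(fs)
        # first down and last up touch the edges; the final down loses its
        # edge-partial up partner: 18 complete cycles remain of 20 periods
        assert len(seg.cycles) == 18
        np.testing.assert_allclose(seg.up_durations, 0.5, atol=0.011)
        np.testing.assert_allclose(seg.down_durations, 0.5, atol=0.011)
        # boundaries land on the constructed level transitions (bin grid)
        (d0, d1), (u0, u1) = seg.cycles[0]
        assert d0 == pytest.approx(1.0, abs=0.01)
        assert u0 == pytest.approx(1.5, abs=0.01)

    def test_stationary_null_raises_no_alternation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8000)
        fs = detection.FeatureSet(x, x, x, combined=x, pca_weights=np.ones(3))
        with pytest.raises(detection.NoAlternationError):
            detection.segment_states(fs)

    def test_generator_agreement_exceeds_090(self, small_fit, small_recording):
        res, truth, params = small_fit
        (rec, _), _ = small_recording
        assert label_agreement(res.segmentation, truth, rec.rate) >= 0.9

    def test_invariance_to_sign_flip_and_gain(self, small_recording):
        """The detected cycles are identical for -5x the raw signal."""
        from slowosc.model import SlowOscillationModel

        (rec, _), _ = small_recording
        flipped = Recording(
            samples=(-5.0 * rec.samples).astype(np.float32), rate=rec.rate
        )
        seg_a = SlowOscillationModel(rec, compute_spectra=False, compute_sampen=False).fit().segmentation
        seg_b = SlowOscillationModel(flipped, compute_spectra=False, compute_sampen=False).fit().segmentation
        assert len(seg_a.cycles) == len(seg_b.cycles)
        a = np.array([u for _, u in seg_a.cycles])
        b = np.array([u for _, u in seg_b.cycles])
        np.testing.assert_allclose(a, b, atol=0.02)

    def test_short_series_rejected(self):
        x = np.random.default_rng(0).normal(size=100)
        fs = detection.FeatureSet(x, x, x, combined=x, pca_weights=np.ones(3))
        with pytest.raises(ValueError, match="10 s"):
            detection.segment_states(fs)


class TestSOMetrics:
    def test_constant_half_second_cycles(self):
        from conftest import make_segmentation

        cycles = [((i, i + 0.5), (i + 0.5, i + 1.0)) for i in range(10)]
        m = detection.so_metrics(make_segmentation(cycles))
        assert m.so_freq_hz == pytest.approx(1.0)
        assert m.cv_freq == 0.0

    def test_two_period_mixture(self):
        """Periods 1 s and 3 s: frequencies {1, 1/3}, mean 2/3, CV sqrt(2)/2."""
        from conftest import make_segmentation

        cycles = [((0, 0.5), (0.5, 1.0)), ((1.0, 2.5), (2.5, 4.0))]
        m = detection.so_metrics(make_segmentation(cycles))
        assert m.so_freq_hz == pytest.approx(2 / 3)
        assert m.cv_freq == pytest.approx(np.sqrt(2) / 2, rel=1e-9)

    def test_printed_pooled_durations_give_printed_cycle_frequency(self):
        from conftest import make_segmentation

        cycles = [((i * 1.71, i * 1.71 + 1.1), (i * 1.71 + 1.1, (i + 1) * 1.71)) for i in range(3)]
        m = detection.so_metrics(make_segmentation(cycles))
        assert m.so_freq_hz == pytest.approx(1 / 1.71, rel=1e-9)

    def test_single_cycle_rejected(self):
        from conftest import make_segmentation

        with pytest.raises(ValueError):
            detection.so_metrics(make_segmentation([((0, 1), (1, 2))]))
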