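"""Model/Results interface over the analysis chain.

``SlowOscillationModel`` wraps the full single-channel pipeline
(fingerprint features -> PCA combination -> Up/Down segmentation -> SO,
firing-rate, entropy and spectral metrics); ``fit()`` returns a
``SlowOscillationResults`` carrying the estimates and a ``summary()``
table.  ``WavePropagationModel`` does the same for multichannel array
recordings (per-channel detection -> wave grouping -> lag clustering ->
propagation speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detection, entropy, mua, spectral, waves
from .io import Recording

__all__ = [
    "SlowOscillationModel",
    "SlowOscillationResults",
    "WavePropagationModel",
    "WavePropagationResults",
]


@dataclass
class SlowOscillationResults:
    """Estimates from one channel's Up/Down analysis."""

    model: "SlowOscillationModel"
    features: detection.FeatureSet
    segmentation: detection.StateSegmentation
    so: detection.SOMetrics
    fr: mua.FRMetrics
    logmua: mua.LogMUASeries
    sampen: entropy.EntropyMetrics | None = None
    spectra: dict[str, spectral.SpectralResult] = field(default_factory=dict)

    def metric_values(self) -> dict[str, float]:
        """Flat metric_name -> value mapping (registry names)."""
        out = {
            "so_frequency_hz": self.so.so_freq_hz,
            "mean_up_s": self.so.mean_up_s,
            "mean_down_s": self.so.mean_down_s,
            "cv_freq": self.so.cv_freq,
            "n_cycles": float(self.so.n_cycles),
            "fr_up": self.fr.fr_up,
            "fr_down": self.fr.fr_down,
        }
        if self.fr.rel_fr is not None:
            out["rel_fr"] = self.fr.rel_fr
        if self.sampen is not None:
            out["sampen_up"] = self.sampen.sampen_up
            out["sampen_down"] = self.sampen.sampen_down
        for state, res in self.spectra.items():
            if res.peak_hz is not None:
                out[f"peak_hz_{state}"] = res.peak_hz
                out[f"peak_excess_{state}"] = res.peak_excess
            if res.fit is not None:
                out[f"alpha_1f_{state}"] = res.fit.alpha
        return out

    def summary(self) -> pd.DataFrame:
        """One-row-per-metric summary table."""
        vals = self.metric_values()
        units = {
            "so_frequency_hz": "Hz",
            "mean_up_s": "s",
            "mean_down_s": "s",
            "cv_freq": "",
            "n_cycles": "",
            "fr_up": "log a.u.",
            "fr_down": "log a.u.",
            "rel_fr": "log a.u.",
            "sampen_up": "nats",
            "sampen_down": "nats",
            "peak_hz_up": "Hz",
            "peak_hz_down": "Hz",
            "peak_excess_up": "",
            "peak_excess_down": "",
            "alpha_1f_up": "",
            "alpha_1f_down": "",
        }
        return pd.DataFrame(
            {
                "metric": list(vals),
                "value": list(vals.values()),
                "unit": [units.get(k, "") for k in vals],
            }
        )

    def plot(self, ax=None):
        """Combined feature series with the detected Up intervals shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = np.arange(self.features.combined.size) * self.features.bin_s
        ax.plot(t, self.features.combined, lw=0.5, color="k")
        ax.axhline(self.segmentation.threshold, color="r", ls="--", lw=0.8)
        for u0, u1 in self.segmentation.up_intervals:
            ax.axvspan(u0, u1, color="orange", alpha=0.25, lw=0)
        ax.set(xlabel="time (s)", ylabel="combined feature (z)")
        return ax


class SlowOscillationModel:
    """Up/Down state analysis of one LFP channel.

    Parameters
    ----------
    recording : Recording
    channel : int
        Channel index to analyze.
    so_cutoff_hz, gamma_band : detection band settings.
    min_state_s, merge_gap_s : segmentation cleanup settings.
    window_samples : Welch window length in samples (native rate);
        None picks ``rate / 4`` Hz-resolution-equivalent (4 Hz bins).
    compute_spectra, compute_sampen : toggle the slower metric blocks.
    """

    def __init__(
        self,
        recording: Recording,
        channel: int = 0,
        *,
        so_cutoff_hz: float = 2.0,
        gamma_band: tuple[float, float] = (20.0, 80.0),
        min_state_s: float = 0.1,
        merge_gap_s: float = 0.05,
        window_samples: int | None = spectral.DEFAULT_WINDOW,
        fit_band: tuple[float, float] = spectral.DEFAULT_FIT_BAND,
        search_band: tuple[float, float] = spectral.DEFAULT_SEARCH_BAND,
        sampen_m: int = 2,
        sampen_r: float = 0.25,
        rel_fr_window_s: float = 0.5,
        compute_spectra: bool = True,
        compute_sampen: bool = True,
    ) -> None:
        self.recording = recording
        self.channel = channel
        self.so_cutoff_hz = so_cutoff_hz
        self.gamma_band = gamma_band
        self.min_state_s = min_state_s
        self.merge_gap_s = merge_gap_s
        self.window_samples = window_samples
        self.fit_band = fit_band
        self.search_band = search_band
        self.sampen_m = sampen_m
        self.sampen_r = sampen_r
        self.rel_fr_window_s = rel_fr_window_s
        self.compute_spectra = compute_spectra
        self.compute_sampen = compute_sampen

    @classmethod
    def from_file(cls, path, channel: int = 0, **kwargs) -> "SlowOscillationModel":
        from .io import read_recording

        return cls(read_recording(path), channel=channel, **kwargs)

    def fit(self) -> SlowOscillationResults:
        rec = self.recording
        env = detection.so_envelope(rec, self.channel, cutoff_hz=self.so_cutoff_hz)
        gvar = detection.gamma_variance_envelope(rec, self.channel, band=self.gamma_band)
        logmua = mua.estimate_logmua(rec, self.channel)
        fs = detection.combine_features_pca(env, gvar, logmua.values)
        seg = detection.segment_states(
            fs, min_state_s=self.min_state_s, merge_gap_s=self.merge_gap_s
        )
        seg.channel = self.channel
        so = detection.so_metrics(seg)
        fr = mua.state_fr(logmua, seg)
        try:
            fr.rel_fr = mua.relative_fr(logmua, seg, window_s=self.rel_fr_window_s)
        except ValueError:
            fr.rel_fr = None

        sampen_metrics = None
        if self.compute_sampen:
            sampen_metrics = entropy.state_sampen(
                logmua, seg, m=self.sampen_m, r_factor=self.sampen_r
            )

        spectra: dict[str, spectral.SpectralResult] = {}
        if self.compute_spectra:
            window = self.window_samples or int(round(rec.rate / 4.0))
            for state in ("up", "down"):
                try:
                    res = spectral.state_psd(rec, self.channel, seg, state, window)
                except ValueError:
                    continue
                try:
                    fit = spectral.fit_one_over_f(res.freqs, res.psd, self.fit_band)
                    res = spectral.power_excess(res.freqs, res.psd, fit, self.search_band)
                except ValueError:
                    pass
                spectra[state] = res

        return SlowOscillationResults(
            model=self,
            features=fs,
            segmentation=seg,
            so=so,
            fr=fr,
            logmua=logmua,
            sampen=sampen_metrics,
            spectra=spectra,
        )


@dataclass
class WavePropagationResults:
    """Wave grouping, lag clusters and propagation speed for an array."""

    model: "WavePropagationModel"
    wave_set: waves.WaveSet
    clusters: waves.WaveClusters
    weighted_speed_mm_s: float

    @property
    def direction_slope(self) -> float:
        """Sign of the lag-vs-position regression (positive = wave travels
        from the first electrode towards the last); informational only."""
        ml = np.nanmean(self.wave_set.lags, axis=0)
        valid = ~np.isnan(ml)
        slope = np.polyfit(self.wave_set.positions_mm[valid], ml[valid], 1)[0]
        return float(np.sign(slope))

    def summary(self) -> pd.DataFrame:
        rows = []
        speeds = self.clusters.speeds_mm_s
        for g in range(self.clusters.k):
            rows.append(
                {
                    "cluster": g,
                    "n_waves": int(round(self.clusters.weights[g] * self.wave_set.n_waves)),
                    "weight": self.clusters.weights[g],
                    "speed_mm_s": speeds[g],
                }
            )
        rows.append(
            {
                "cluster": "weighted",
                "n_waves": self.wave_set.n_waves,
                "weight": 1.0,
                "speed_mm_s": self.weighted_speed_mm_s,
            }
        )
        return pd.DataFrame(rows)


class WavePropagationModel:
    """Traveling-wave speed estimation from per-channel Up onsets.

    Build either from explicit onset lists (``WavePropagationModel(
    onsets, positions_mm)``) or from an array recording with
    :meth:`from_recording`, which runs Up/Down detection on every
    channel first.
    """

    def __init__(
        self,
        onsets: list[np.ndarray],
        positions_mm,
        *,
        min_channels: int = waves.MIN_CHANNELS,
        k: int = 5,
        seed: int = 0,
    ) -> None:
        self.onsets = [np.asarray(o, dtype=float) for o in onsets]
        self.positions_mm = np.asarray(positions_mm, dtype=float)
        self.min_channels = min_channels
        self.k = k
        self.seed = seed

    @classmethod
    def from_recording(cls, recording: Recording, *, detection_kwargs: dict | None = None, **kwargs):
        """Detect Up onsets on every channel of an array recording."""
        detection_kwargs = dict(detection_kwargs or {})
        detection_kwargs.setdefault("compute_spectra", False)
        detection_kwargs.setdefault("compute_sampen", False)
        onsets = []
        for c in range(recording.n_channels):
            res = SlowOscillationModel(recording, channel=c, **detection_kwargs).fit()
            onsets.append(np.array([u0 for u0, _ in res.segmentation.up_intervals]))
        return cls(onsets, recording.positions_mm, **kwargs)

    def fit(self) -> WavePropagationResults:
        ws = waves.group_waves(
            self.onsets, min_channels=self.min_channels, positions_mm=self.positions_mm
        )
        wc = waves.cluster_lags(ws, k=self.k, seed=self.seed)
        speed = waves.propagation_speed(wc)
        return WavePropagationResults(
            model=self, wave_set=ws, clusters=wc, weighted_speed_mm_s=speed
        )
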