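"""logMUA estimation and firing-rate metrics.

Multi-unit activity (MUA) is estimated as spectral power of the
wide-band extracellular signal between 200 and 1500 Hz in non-overlapping
5 ms windows; high-frequency Fourier components scale with the spiking
of the nearby population, so this band serves as a population
firing-rate proxy.  Values are log-scaled (natural log, floored) to
balance the large fluctuations contributed by the closest units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording

__all__ = ["LogMUASeries", "FRMetrics", "estimate_logmua", "state_fr", "relative_fr"]

MUA_BAND = (200.0, 1500.0)
MIN_RATE_HZ = 3000.0


@dataclass
class LogMUASeries:
    """Log-scaled MUA power per 5 ms bin."""

    values: np.ndarray
    bin_s: float = 0.005
    band: tuple[float, float] = MUA_BAND

    @property
    def times(self) -> np.ndarray:
        """Bin-center times in seconds."""
        return (np.arange(self.values.size) + 0.5) * self.bin_s

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FRMetrics:
    """Absolute and relative firing-rate metrics (log arbitrary units)."""

    fr_up: float
    fr_down: float
    rel_fr: float | None = None


def estimate_logmua(
    rec: Recording, channel: int = 0, bin_s: float = 0.005, band: tuple[float, float] = MUA_BAND
) -> LogMUASeries:
    """Estimate logMUA: band power per non-overlapping 5 ms window.

    The signal is first band-pass filtered to ``band`` (zero-phase), so
    slow LFP components cannot leak through the short window; each
    window's periodogram (rectangular taper) is then averaged over
    ``band``, floored at 1e-12 x the series median, and log-transformed.
    """
    if rec.rate < MIN_RATE_HZ:
        raise ValueError(
            f"sampling rate {rec.rate} Hz too low for the {band[0]:.0f}-{band[1]:.0f} Hz "
            f"MUA band; need >= {MIN_RATE_HZ:.0f} Hz"
        )
    from scipy.signal import butter, sosfiltfilt

    nyq = rec.rate / 2
    top = min(band[1], 0.99 * nyq)
    sos = butter(4, [band[0] / nyq, top / nyq], btype="bandpass", output="sos")
    x = sosfiltfilt(sos, np.asarray(rec.channel(channel), dtype=np.float64))
    w = int(round(bin_s * rec.rate))
    n_bins = x.size // w
    frames = x[: n_bins * w].reshape(n_bins, w)
    spec = np.fft.rfft(frames, axis=1)
    psd = (np.abs(spec) ** 2) / (w * rec.rate)  # one-sided density up to factor 2
    freqs = np.fft.rfftfreq(w, d=1.0 / rec.rate)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= min(hi, rec.rate / 2))
    power = psd[:, mask].mean(axis=1)
    floor = 1e-12 * max(np.median(power), np.finfo(float).tiny)
    values = np.log(np.maximum(power, floor))
    return LogMUASeries(values=values, bin_s=bin_s, band=band)


def _interval_mask(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Bin-center membership in a set of half-open [start, end) intervals."""
    mask = np.zeros(times.size, dtype=bool)
    for start, end in intervals:
        mask |= (times >= start) & (times < end)
    return mask


def state_fr(mua: LogMUASeries, seg) -> FRMetrics:
    """Mean logMUA over Up and over Down intervals (bin-center assignment)."""
    times = mua.times
    up_mask = _interval_mask(times, seg.up_intervals)
    down_mask = _interval_mask(times, seg.down_intervals)
    if not up_mask.any() or not down_mask.any():
        raise ValueError("a state class has no logMUA bins")
    return FRMetrics(
        fr_up=float(mua.values[up_mask].mean()),
        fr_down=float(mua.values[down_mask].mean()),
    )


def relative_fr(mua: LogMUASeries, seg, window_s: float = 0.5) -> float:
    """Peak of the Down-normalized average logMUA waveform at Down-to-Up.

    The logMUA is averaged across all Down-to-Up transitions over
    ``[-window_s, +window_s]``, the mean of the pre-transition (Down)
    portion is subtracted, and the maximum of the post-transition
    portion is returned.  The order matters: averaging precedes the
    maximum, so asynchronous single-transition peaks do not inflate it.
    """
    transitions = [up[0] for _, up in seg.cycles]
    if len(transitions) < 5:
        raise ValueError(f"need >= 5 Down-to-Up transitions, have {len(transitions)}")
    half = int(round(window_s / mua.bin_s))
    windows = []
    for t in transitions:
        center = int(round(t / mua.bin_s))
        if center - half < 0 or center + half + 1 > mua.values.size:
            continue
        windows.append(mua.values[center - half : center + half + 1])
    if len(windows) < 5:
        raise ValueError("fewer than 5 transitions with a full window inside the series")
    avg = np.mean(windows, axis=0)
    baseline = avg[:half].mean()  # lags < 0: pre-transition Down portion
    return float((avg[half:] - baseline).max())
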