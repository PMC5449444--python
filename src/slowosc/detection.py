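"""Up/Down state detection from three LFP fingerprints.

An Up state leaves three simultaneous signatures in the extracellular
signal: a slow LFP deflection, a rise in gamma-band activity, and
population firing.  Each is extracted as a time series on a common 5 ms
grid — (1) the slow-oscillation envelope, (2) the envelope of the
variance of the gamma-filtered LFP, and (3) logMUA — and combined into
a single series by projecting onto the first principal component of the
z-scored features.  Because the three features live in disjoint
frequency bands, the combination is robust to band-limited noise or
electrode malfunction.  Thresholding the combined series at the trough
between its two modes yields the Up/Down segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .io import Recording
from .mua import estimate_logmua

__all__ = [
    "FeatureSet",
    "StateSegmentation",
    "SOMetrics",
    "NoAlternationError",
    "so_envelope",
    "gamma_variance_envelope",
    "combine_features_pca",
    "segment_states",
    "so_metrics",
]

BIN_S = 0.005


class NoAlternationError(RuntimeError):
    """The combined feature series shows no Up/Down bimodality."""


@dataclass
class FeatureSet:
    """The three state fingerprints on a common 5 ms grid, plus their PCA mix."""

    so_env: np.ndarray
    gamma_var: np.ndarray
    logmua: np.ndarray
    bin_s: float = BIN_S
    pca_weights: np.ndarray | None = None
    combined: np.ndarray | None = None


@dataclass
class StateSegmentation:
    """Alternating Down/Up cycles detected in one channel.

    ``cycles`` is an ordered list of ``((down_start, down_end),
    (up_start, up_end))`` pairs in seconds, half-open intervals, with
    ``down_end == up_start``.  Partial states at the recording edges are
    excluded from ``cycles`` but still reflected in ``bin_labels``.
    """

    cycles: list[tuple[tuple[float, float], tuple[float, float]]]
    bin_s: float = BIN_S
    channel: int | None = None
    threshold: float | None = None
    #: raw per-bin Up labels after merge/min-duration cleanup (incl. edges)
    bin_labels: np.ndarray | None = None

    @property
    def up_intervals(self) -> list[tuple[float, float]]:
        return [up for _, up in self.cycles]

    @property
    def down_intervals(self) -> list[tuple[float, float]]:
        return [down for down, _ in self.cycles]

    @property
    def n_up(self) -> int:
        return len(self.cycles)

    @property
    def n_down(self) -> int:
        return len(self.cycles)

    @property
    def up_durations(self) -> np.ndarray:
        return np.array([u1 - u0 for u0, u1 in self.up_intervals])

    @property
    def down_durations(self) -> np.ndarray:
        return np.array([d1 - d0 for d0, d1 in self.down_intervals])


@dataclass
class SOMetrics:
    """Slow-oscillation summary metrics.

    ``so_freq_hz`` is the mean of per-cycle frequencies 1/(up+down) and
    ``cv_freq`` their coefficient of variation (sample SD / mean).
    """

    so_freq_hz: float
    mean_up_s: float
    mean_down_s: float
    cv_freq: float
    n_cycles: int


def _bin_mean(x: np.ndarray, w: int) -> np.ndarray:
    n_bins = x.size // w
    return x[: n_bins * w].reshape(n_bins, w).mean(axis=1)


def _highband_activity(x: np.ndarray, rate: float) -> np.ndarray:
    """Crude high-frequency activity trace used only to orient the SO envelope."""
    nyq = rate / 2
    lo = 20.0
    hi = min(0.8 * nyq, 200.0)
    sos = butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return gaussian_filter1d(np.abs(sosfiltfilt(sos, x)), sigma=0.05 * rate)


def so_envelope(
    rec: Recording, channel: int = 0, cutoff_hz: float = 2.0, bin_s: float = BIN_S
) -> np.ndarray:
    """Slow-oscillation envelope: low-passed LFP, oriented so Up is positive.

    The low-passed signal is sign-oriented by correlating it with a
    high-frequency activity trace (Up states carry the firing), which
    makes the whole detection chain agnostic to the recording's polarity
    (deep-layer Up deflections are negative).
    """
    if rec.rate < 200:
        raise ValueError("sampling rate must be >= 200 Hz")
    nyq = rec.rate / 2
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    x = np.asarray(rec.channel(channel), dtype=np.float64)
    sos = butter(4, cutoff_hz / nyq, btype="lowpass", output="sos")
    slow = sosfiltfilt(sos, x)
    activity = _highband_activity(x, rec.rate)
    sgn = np.corrcoef(slow, activity)[0, 1]
    if np.isfinite(sgn) and sgn < 0:
        slow = -slow
    return _bin_mean(slow, int(round(bin_s * rec.rate)))


def gamma_variance_envelope(
    rec: Recording,
    channel: int = 0,
    band: tuple[float, float] = (20.0, 80.0),
    bin_s: float = BIN_S,
    smooth_s: float = 0.05,
) -> np.ndarray:
    """Envelope of the variance of the gamma-filtered LFP.

    Band-pass (zero-phase), variance within each 5 ms bin, then a
    ``smooth_s`` moving average.
    """
    nyq = rec.rate / 2
    if band[1] >= nyq:
        raise ValueError(f"gamma band top {band[1]} Hz must be below Nyquist ({nyq} Hz)")
    x = np.asarray(rec.channel(channel), dtype=np.float64)
    sos = butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    g = sosfiltfilt(sos, x)
    w = int(round(bin_s * rec.rate))
    n_bins = g.size // w
    frames = g[: n_bins * w].reshape(n_bins, w)
    var = frames.var(axis=1) + frames.mean(axis=1) ** 2  # power about zero
    k = max(int(round(smooth_s / bin_s)), 1)
    return uniform_filter1d(var, size=k)


def combine_features_pca(
    so_env: np.ndarray, gamma_var: np.ndarray, logmua: np.ndarray, bin_s: float = BIN_S
) -> FeatureSet:
    """Combine the three fingerprints by PCA weighting.

    Each series is z-scored; the combined series is the projection onto
    the first principal component, oriented to correlate positively
    with logMUA.  A constant (degenerate) feature gets weight 0 with a
    warning.
    """
    series = [np.asarray(s, dtype=np.float64) for s in (so_env, gamma_var, logmua)]
    n = min(s.size for s in series)
    if any(s.size != n for s in series):
        series = [s[:n] for s in series]
    Z = np.empty((3, n))
    ok = np.ones(3, dtype=bool)
    names = ("so_env", "gamma_var", "logmua")
    for i, s in enumerate(series):
        sd = s.std()
        if sd == 0:
            warnings.warn(f"feature {names[i]} is constant; weight set to 0", stacklevel=2)
            ok[i] = False
            Z[i] = 0.0
        else:
            Z[i] = (s - s.mean()) / sd
    if not ok.any():
        raise ValueError("all three features are constant")
    C = (Z[ok] @ Z[ok].T) / n
    eigvals, eigvecs = np.linalg.eigh(C)
    w_active = eigvecs[:, -1]
    weights = np.zeros(3)
    weights[ok] = w_active
    combined = weights @ Z
    # orient so Up (high firing) maps to high combined values
    if ok[2]:
        ref = Z[2]
    else:
        ref = Z[ok.argmax()]
    if np.dot(combined, ref) < 0:
        weights = -weights
        combined = -combined
    return FeatureSet(
        so_env=series[0],
        gamma_var=series[1],
        logmua=series[2],
        bin_s=bin_s,
        pca_weights=weights,
        combined=combined,
    )


def _histogram_trough(x: np.ndarray) -> float | None:
    """Threshold at the trough between the two modes of a smoothed histogram."""
    n_bins = int(np.clip(np.sqrt(x.size), 50, 200))
    hist, edges = np.histogram(x, bins=n_bins)
    smooth = gaussian_filter1d(hist.astype(float), sigma=2.0)
    peaks, props = find_peaks(smooth, prominence=0.05 * smooth.max())
    if peaks.size < 2:
        return None
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    lo, hi = np.sort(top2)
    trough = lo + int(np.argmin(smooth[lo : hi + 1]))
    # demand a real dip between the modes
    if smooth[trough] > 0.8 * min(smooth[lo], smooth[hi]):
        return None
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[trough])


def _kmeans_threshold(x: np.ndarray, min_separation: float = 2.0) -> float:
    """2-means fallback threshold; errors if the split is not a real bimodality.

    Separation is Ashman's D = |c1 - c0| / sqrt(s0^2 + s1^2); a 2-means
    split of *unimodal* data (Gaussian or skewed) stays below ~1.95
    while genuinely bimodal state data exceeds 2.2.
    """
    from sklearn.cluster import KMeans

    sub = x if x.size <= 20000 else x[:: x.size // 20000 + 1]
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(sub.reshape(-1, 1))
    c = np.sort(km.cluster_centers_.ravel())
    sds = [sub[km.labels_ == i].std() for i in range(2)]
    spread = np.sqrt(sds[0] ** 2 + sds[1] ** 2)
    d = np.inf if spread == 0 else abs(c[1] - c[0]) / spread
    if d < min_separation:
        raise NoAlternationError(
            f"no state alternation detected (cluster separation D = {d:.2f} < "
            f"{min_separation})"
        )
    return float(c.mean())


def _runs(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode: list of (start, end, value) half-open index runs."""
    changes = np.flatnonzero(np.diff(labels.astype(np.int8))) + 1
    bounds = np.concatenate([[0], changes, [labels.size]])
    return [(int(b0), int(b1), bool(labels[b0])) for b0, b1 in zip(bounds[:-1], bounds[1:])]


def segment_states(
    fs: FeatureSet,
    min_state_s: float = 0.1,
    merge_gap_s: float = 0.05,
    threshold: float | None = None,
) -> StateSegmentation:
    """Threshold the combined series into an alternating Up/Down segmentation.

    The threshold sits at the trough between the two histogram modes
    (2-means fallback when no clean trough exists); above-threshold runs
    are Up.  Down gaps shorter than ``merge_gap_s`` are merged into the
    surrounding Up state, runs shorter than ``min_state_s`` are absorbed
    into their flanking state, and partial states at the edges are
    dropped from the cycle list.
    """
    x = fs.combined
    if x is None:
        raise ValueError("FeatureSet has no combined series; run combine_features_pca")
    if x.size * fs.bin_s < 10.0:
        raise ValueError("need at least 10 s of combined series")
    if threshold is None:
        threshold = _histogram_trough(x)
        if threshold is None:
            threshold = _kmeans_threshold(x)
    labels = x > threshold

    min_bins = max(int(round(min_state_s / fs.bin_s)), 1)
    gap_bins = max(int(round(merge_gap_s / fs.bin_s)), 1)

    # merge short Down gaps flanked by Up
    runs = _runs(labels)
    for i, (b0, b1, val) in enumerate(runs):
        if not val and 0 < i < len(runs) - 1 and (b1 - b0) < gap_bins:
            labels[b0:b1] = True
    # absorb short runs into flanking states, shortest first
    while True:
        runs = _runs(labels)
        interior = [r for r in runs[1:-1] if (r[1] - r[0]) < min_bins]
        if not interior:
            break
        b0, b1, val = min(interior, key=lambda r: r[1] - r[0])
        labels[b0:b1] = not val

    runs = _runs(labels)
    # drop partial edge states: cycles only from complete Down->Up pairs
    cycles = []
    for i in range(1, len(runs) - 1):
        b0, b1, val = runs[i]
        if not val and i + 1 < len(runs) - 1 and runs[i + 1][2]:
            u0, u1, _ = runs[i + 1]
            cycles.append(
                (
                    (b0 * fs.bin_s, b1 * fs.bin_s),
                    (u0 * fs.bin_s, u1 * fs.bin_s),
                )
            )
    return StateSegmentation(
        cycles=cycles, bin_s=fs.bin_s, threshold=float(threshold), bin_labels=labels
    )


def compute_features(
    rec: Recording,
    channel: int = 0,
    so_cutoff_hz: float = 2.0,
    gamma_band: tuple[float, float] = (20.0, 80.0),
    bin_s: float = BIN_S,
) -> FeatureSet:
    """Compute and PCA-combine all three fingerprints for one channel."""
    env = so_envelope(rec, channel, cutoff_hz=so_cutoff_hz, bin_s=bin_s)
    gvar = gamma_variance_envelope(rec, channel, band=gamma_band, bin_s=bin_s)
    mua = estimate_logmua(rec, channel, bin_s=bin_s)
    return combine_features_pca(env, gvar, mua.values, bin_s=bin_s)


def so_metrics(seg: StateSegmentation) -> SOMetrics:
    """Per-cycle SO frequency, durations and frequency CV from a segmentation."""
    if len(seg.cycles) < 2:
        raise ValueError(f"need >= 2 complete cycles, have {len(seg.cycles)}")
    up = seg.up_durations
    down = seg.down_durations
    freqs = 1.0 / (up + down)
    mean_f = float(freqs.mean())
    return SOMetrics(
        so_freq_hz=mean_f,
        mean_up_s=float(up.mean()),
        mean_down_s=float(down.mean()),
        cv_freq=float(freqs.std(ddof=1) / mean_f),
        n_cycles=len(seg.cycles),
    )
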