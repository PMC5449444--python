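"""Per-state Welch spectra, 1/f fit and power excess.

The power spectral density is estimated separately inside Up and Down
states with Welch's method (Hann taper, 50%-overlapped windows of 5000
samples at the native rate), drawing windows only from within
same-state segments.  The aperiodic background is fitted as A/f^alpha
by robust log-log regression, and the *power excess* — the ratio of the
PSD to the fitted decay — localizes oscillatory peaks (beta-gamma
synchronization) independently of broadband power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .io import Recording

__all__ = ["OneOverFFit", "SpectralResult", "state_psd", "fit_one_over_f", "power_excess"]

DEFAULT_WINDOW = 5000
DEFAULT_FIT_BAND = (5.0, 100.0)
DEFAULT_SEARCH_BAND = (10.0, 90.0)


@dataclass
class OneOverFFit:
    """Aperiodic fit P(f) = A / f**alpha."""

    A: float
    alpha: float

    def __call__(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        with np.errstate(divide="ignore"):
            return self.A / f**self.alpha


@dataclass
class SpectralResult:
    """PSD of one state plus its 1/f fit and power-excess curve."""

    freqs: np.ndarray
    psd: np.ndarray
    fit: OneOverFFit | None = None
    excess: np.ndarray | None = None
    peak_hz: float | None = None
    peak_excess: float | None = None
    flat: bool = False
    n_windows: int = 0


def state_psd(
    rec: Recording,
    channel: int,
    seg,
    state: str = "up",
    window_samples: int = DEFAULT_WINDOW,
) -> SpectralResult:
    """Welch PSD restricted to Up (or Down) segments.

    Only segments at least one window long contribute (no cross-segment
    concatenation); segment spectra are averaged weighted by each
    segment's window count.
    """
    if state.lower() not in ("up", "down"):
        raise ValueError("state must be 'up' or 'down'")
    intervals = seg.up_intervals if state.lower() == "up" else seg.down_intervals
    x = np.asarray(rec.channel(channel), dtype=np.float64)
    rate = rec.rate
    psd_sum = None
    total_windows = 0
    for start, end in intervals:
        i0, i1 = int(round(start * rate)), int(round(end * rate))
        i1 = min(i1, x.size)
        if i1 - i0 < window_samples:
            continue
        f, p = welch(
            x[i0:i1],
            fs=rate,
            window="hann",
            nperseg=window_samples,
            noverlap=window_samples // 2,
            detrend=False,
        )
        k = 1 + (i1 - i0 - window_samples) // (window_samples // 2)
        psd_sum = p * k if psd_sum is None else psd_sum + p * k
        total_windows += k
    if psd_sum is None:
        raise ValueError(
            f"no {state} segment is at least {window_samples} samples "
            f"({window_samples / rate:.3f} s) long"
        )
    return SpectralResult(freqs=f, psd=psd_sum / total_windows, n_windows=total_windows)


def fit_one_over_f(
    freqs: np.ndarray,
    psd: np.ndarray,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
) -> OneOverFFit:
    """Fit A/f^alpha by two-pass robust log-log regression.

    Bins more than 2 SD *above* the first-pass fit (oscillatory peaks)
    are excluded and the line refitted.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    mask = (freqs >= fit_band[0]) & (freqs <= fit_band[1]) & (freqs > 0) & (psd > 0)
    if mask.sum() < 5:
        raise ValueError(f"fewer than 5 usable bins in fit band {fit_band}")
    lf, lp = np.log(freqs[mask]), np.log(psd[mask])
    for _ in range(2):
        slope, intercept = np.polyfit(lf, lp, 1)
        resid = lp - (slope * lf + intercept)
        sd = resid.std()
        keep = resid <= 2 * sd if sd > 0 else np.ones_like(resid, dtype=bool)
        if keep.sum() < 5 or keep.all():
            break
        lf, lp = lf[keep], lp[keep]
    slope, intercept = np.polyfit(lf, lp, 1)
    return OneOverFFit(A=float(np.exp(intercept)), alpha=float(-slope))


def power_excess(
    freqs: np.ndarray,
    psd: np.ndarray,
    fit: OneOverFFit,
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND,
) -> SpectralResult:
    """Power excess = PSD / fitted 1/f decay, and its peak in ``search_band``.

    On an exactly aperiodic input the excess is flat (== 1); the result
    is then flagged ``flat`` and the peak pinned at the band's lower
    edge.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    pos = freqs > 0
    excess = np.full_like(psd, np.nan)
    excess[pos] = psd[pos] / fit(freqs[pos])
    band = pos & (freqs >= search_band[0]) & (freqs <= search_band[1])
    if not band.any():
        raise ValueError(f"search band {search_band} outside the PSD grid")
    e_band = excess[band]
    f_band = freqs[band]
    flat = bool(np.ptp(e_band) <= 1e-6 * max(np.abs(e_band).max(), 1e-300))
    if flat:
        peak_hz = float(f_band[0])
        peak_excess = float(e_band[0])
    else:
        i = int(np.argmax(e_band))
        peak_hz = float(f_band[i])
        peak_excess = float(e_band[i])
    return SpectralResult(
        freqs=freqs,
        psd=psd,
        fit=fit,
        excess=excess,
        peak_hz=peak_hz,
        peak_excess=peak_excess,
        flat=flat,
    )
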