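"""Traveling-wave grouping, lag clustering and propagation speed.

Up-state onsets detected independently on each electrode of a linear
array are grouped into waves by a recursive windowing pass (a wave is a
set of onsets, at most one per channel, falling inside a time window
that shrinks at each iteration).  Partial waves with disjoint channel
sets are recollected into full waves, and waves covering fewer than 10
electrodes are rejected.  Relative onset lags (onset minus the wave's
mean onset) are clustered with k-means into up to five propagation
patterns; each pattern's speed is the electrode distance between the
extreme mean lags divided by their lag difference, and the recording's
speed is the cluster-weighted mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveSet",
    "WaveClusters",
    "group_waves",
    "cluster_lags",
    "propagation_speed",
]

MIN_CHANNELS = 10


@dataclass
class WaveSet:
    """Waves of per-channel Up onsets with relative lags.

    ``onsets`` is (n_waves, n_channels) with NaN for non-participating
    channels; ``lags`` subtracts each wave's mean onset over its
    participants, so lags sum to zero per wave.
    """

    onsets: np.ndarray
    positions_mm: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.atleast_2d(np.asarray(self.onsets, dtype=float))
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)

    @property
    def n_waves(self) -> int:
        return self.onsets.shape[0]

    @property
    def n_channels(self) -> int:
        return self.onsets.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.onsets)

    @property
    def lags(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(self.onsets, axis=1, keepdims=True)
        return self.onsets - means


@dataclass
class WaveClusters:
    """k-means clusters of wave lag patterns with per-cluster speeds."""

    assignments: np.ndarray
    mean_lags: np.ndarray  # (k, n_channels), NaN where no participant
    sem_lags: np.ndarray
    weights: np.ndarray  # proportion of waves per cluster
    positions_mm: np.ndarray
    k: int

    @property
    def speeds_mm_s(self) -> np.ndarray:
        speeds = np.full(self.k, np.nan)
        for g in range(self.k):
            speeds[g] = _cluster_speed(self.mean_lags[g], self.positions_mm)
        return speeds

    @property
    def weighted_speed(self) -> float:
        return propagation_speed(self)


def group_waves(
    onsets: list[np.ndarray],
    min_channels: int = MIN_CHANNELS,
    positions_mm: np.ndarray | None = None,
    shrink: float = 0.75,
    min_window_s: float = 0.02,
    max_iter: int = 30,
) -> WaveSet:
    """Group per-channel onset lists into waves by recursive windowing.

    The initial window is half the median inter-onset interval; each
    iteration assigns every onset to the nearest provisional wave time
    (one onset per channel per wave, nearest wins), recomputes wave
    times, shrinks the window by ``shrink`` and repeats until the
    assignment is stable or the window drops below ``min_window_s``.
    Partial waves with disjoint channel sets whose spans overlap are
    then recollected into full waves; waves with fewer than
    ``min_channels`` participants are rejected.
    """
    n_ch = len(onsets)
    usable = sum(1 for o in onsets if len(o) > 0)
    if usable < min_channels:
        raise ValueError(f"only {usable} channels with onsets; need >= {min_channels}")
    if positions_mm is None:
        positions_mm = np.arange(n_ch, dtype=float)
    positions_mm = np.asarray(positions_mm, dtype=float)

    chan_idx = np.concatenate([np.full(len(o), c) for c, o in enumerate(onsets)])
    times = np.concatenate([np.asarray(o, dtype=float) for o in onsets])
    order = np.argsort(times, kind="stable")
    times, chan_idx = times[order], chan_idx[order]

    intervals = np.concatenate(
        [np.diff(np.sort(o)) for o in onsets if len(o) > 1]
    )
    if intervals.size == 0:
        raise ValueError("need channels with at least 2 onsets to set the window")
    window = 0.5 * float(np.median(intervals))

    # initial provisional waves: greedy sweep over the pooled, sorted onsets
    wave_times = _greedy_sweep(times, chan_idx, window)
    assign = np.full(times.size, -1)
    for _ in range(max_iter):
        new_assign = _assign(times, chan_idx, wave_times, window)
        wave_times = _recompute(times, new_assign, wave_times.size)
        stable = np.array_equal(new_assign, assign)
        assign = new_assign
        if stable or window * shrink < min_window_s:
            break
        window *= shrink

    waves = _collect(times, chan_idx, assign, wave_times, n_ch)
    waves = _recollect(waves, window)
    keep = [w for w in waves if np.sum(~np.isnan(w)) >= min_channels]
    if not keep:
        return WaveSet(onsets=np.empty((0, n_ch)), positions_mm=positions_mm)
    return WaveSet(onsets=np.vstack(keep), positions_mm=positions_mm)


def _greedy_sweep(times: np.ndarray, chans: np.ndarray, window: float) -> np.ndarray:
    wave_times = []
    members: set[int] = set()
    t0 = None
    acc: list[float] = []
    for t, c in zip(times, chans):
        if t0 is None or t - np.mean(acc) > window or c in members:
            if acc:
                wave_times.append(np.mean(acc))
            t0, members, acc = t, {c}, [t]
        else:
            members.add(c)
            acc.append(t)
    if acc:
        wave_times.append(np.mean(acc))
    return np.asarray(wave_times)


def _assign(
    times: np.ndarray, chans: np.ndarray, wave_times: np.ndarray, window: float
) -> np.ndarray:
    """Assign each onset to the nearest wave within the window, one per channel."""
    assign = np.full(times.size, -1)
    if wave_times.size == 0:
        return assign
    idx = np.searchsorted(wave_times, times)
    left = np.clip(idx - 1, 0, wave_times.size - 1)
    right = np.clip(idx, 0, wave_times.size - 1)
    d_left = np.abs(times - wave_times[left])
    d_right = np.abs(times - wave_times[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    ok = dist <= window
    # resolve one-onset-per-channel-per-wave: closest onset wins
    order = np.argsort(dist, kind="stable")
    taken: set[tuple[int, int]] = set()
    for i in order:
        if not ok[i]:
            continue
        key = (int(nearest[i]), int(chans[i]))
        if key in taken:
            continue
        taken.add(key)
        assign[i] = nearest[i]
    return assign


def _recompute(times: np.ndarray, assign: np.ndarray, n_waves: int) -> np.ndarray:
    sums = np.zeros(n_waves)
    counts = np.zeros(n_waves)
    valid = assign >= 0
    np.add.at(sums, assign[valid], times[valid])
    np.add.at(counts, assign[valid], 1)
    out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    keep = ~np.isnan(out)
    return np.sort(out[keep])


def _collect(
    times: np.ndarray,
    chans: np.ndarray,
    assign: np.ndarray,
    wave_times: np.ndarray,
    n_ch: int,
) -> list[np.ndarray]:
    """Materialize assignment into per-wave onset rows (NaN = absent channel)."""
    waves = []
    for w in range(wave_times.size):
        sel = assign == w
        if not sel.any():
            continue
        row = np.full(n_ch, np.nan)
        row[chans[sel].astype(int)] = times[sel]
        waves.append(row)
    return waves


def _recollect(waves: list[np.ndarray], window: float) -> list[np.ndarray]:
    """Merge time-compatible partial waves with disjoint channel masks."""
    waves = sorted(waves, key=lambda w: np.nanmean(w))
    merged: list[np.ndarray] = []
    for w in waves:
        if merged:
            prev = merged[-1]
            disjoint = not np.any(~np.isnan(prev) & ~np.isnan(w))
            if disjoint and abs(np.nanmean(w) - np.nanmean(prev)) <= 2 * window:
                merged[-1] = np.where(np.isnan(prev), w, prev)
                continue
        merged.append(w.copy())
    return merged


def cluster_lags(ws: WaveSet, k: int = 5, seed: int = 0, n_init: int = 50) -> WaveClusters:
    """Cluster wave lag patterns into up to ``k`` groups with k-means.

    ``k`` is capped at the number of waves.  Missing-channel lags are
    imputed by the per-channel mean first and by the assigned cluster's
    mean on a refinement pass.
    """
    from sklearn.cluster import KMeans

    if ws.n_waves < 1:
        raise ValueError("need at least one wave")
    k = min(k, ws.n_waves)
    lags = ws.lags
    mask = ws.mask
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(lags, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(mask, lags, col_mean[None, :])

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    # refinement: impute missing entries by assigned cluster mean, refit once
    for g in range(k):
        sel = km.labels_ == g
        if sel.any():
            X[sel] = np.where(mask[sel], lags[sel], km.cluster_centers_[g][None, :])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)

    mean_lags = np.full((k, ws.n_channels), np.nan)
    sem_lags = np.full((k, ws.n_channels), np.nan)
    weights = np.zeros(k)
    for g in range(k):
        sel = km.labels_ == g
        weights[g] = sel.mean()
        if not sel.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_lags[g] = np.nanmean(lags[sel], axis=0)
            counts = mask[sel].sum(axis=0)
            sd = np.nanstd(lags[sel], axis=0, ddof=1)
        sem_lags[g] = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    return WaveClusters(
        assignments=km.labels_.copy(),
        mean_lags=mean_lags,
        sem_lags=sem_lags,
        weights=weights,
        positions_mm=ws.positions_mm,
        k=k,
    )


def _cluster_speed(mean_lags: np.ndarray, positions: np.ndarray) -> float:
    valid = ~np.isnan(mean_lags)
    if valid.sum() < 2:
        return np.nan
    lags = mean_lags[valid]
    pos = positions[valid]
    i_max, i_min = int(np.argmax(lags)), int(np.argmin(lags))
    spread = lags[i_max] - lags[i_min]
    if spread <= 0:
        return np.nan
    return float(abs(pos[i_max] - pos[i_min]) / spread)


def propagation_speed(wc: WaveClusters) -> float:
    """Weighted mean propagation speed over clusters (mm/s).

    Per cluster, speed is the distance between the electrodes showing
    the maximum and minimum mean lags divided by their lag difference.
    Clusters with zero lag spread have undefined speed and are excluded
    with their weight renormalized (a warning is emitted).
    """
    speeds = wc.speeds_mm_s
    valid = np.isfinite(speeds) & (wc.weights > 0)
    if not valid.any():
        raise ValueError("no cluster has a defined propagation speed")
    if (~valid & (wc.weights > 0)).any():
        warnings.warn(
            "clusters with zero lag spread excluded from the weighted speed",
            stacklevel=2,
        )
    w = wc.weights[valid] / wc.weights[valid].sum()
    return float(np.sum(w * speeds[valid]))
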