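"""Sample entropy of the logMUA series, computed per state.

SampEn(m, r, N) is the negative natural log of the conditional
probability that two sequences similar for m points (Chebyshev distance
<= r) remain similar at point m+1, self-matches excluded.  Lower values
mean a more regular, predictable signal.  Following the convention of
the physiological-complexity literature, m = 2 and r = 0.25 x the
standard deviation of the analyzed segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EntropyMetrics", "sample_entropy", "state_sampen"]


@dataclass
class EntropyMetrics:
    """Per-state mean sample entropy (nats)."""

    sampen_up: float
    sampen_down: float
    m: int
    r_factor: float
    n_up_used: int
    n_down_used: int
    n_up_skipped: int = 0
    n_down_skipped: int = 0


def sample_entropy(series: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """SampEn of a 1-D series with absolute tolerance ``r_abs``.

    Counts template pairs (i < j, i != j) of length ``m`` within
    Chebyshev distance ``r_abs`` (B) and of length ``m + 1`` (A) over
    the first ``N - m`` templates, and returns ``-ln(A / B)``.  Returns
    NaN when either count is zero (entropy undefined).
    """
    x = np.asarray(series, dtype=np.float64)
    if m < 1:
        raise ValueError("m must be >= 1")
    if x.size < m + 2:
        raise ValueError(f"series length {x.size} < m + 2 = {m + 2}")
    if r_abs is None or r_abs < 0:
        raise ValueError("r_abs must be a non-negative absolute tolerance")

    n_templates = x.size - m  # templates that admit an (m+1)-extension
    # embed: rows are templates of length m+1 starting at i = 0..N-m-1
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    # pairwise Chebyshev distances over the first m points and over m+1 points
    diff = np.abs(emb[:, None, :] - emb[None, :, :])
    d_m = diff[:, :, :m].max(axis=2)
    d_m1 = diff.max(axis=2)
    iu = np.triu_indices(n_templates, k=1)  # i < j: excludes self-matches
    B = int(np.count_nonzero(d_m[iu] <= r_abs))
    A = int(np.count_nonzero(d_m1[iu] <= r_abs))
    if B == 0 or A == 0:
        return float("nan")
    return float(-np.log(A / B))


def state_sampen(
    mua,
    seg,
    m: int = 2,
    r_factor: float = 0.25,
    min_bins: int = 10,
    r_abs: float | None = None,
) -> EntropyMetrics:
    """SampEn per Up and per Down state, averaged over homologous periods.

    For each state segment the logMUA bins are extracted; segments with
    fewer than ``min_bins`` bins are skipped.  The tolerance is
    ``r_factor`` x the segment's SD (or the fixed ``r_abs`` if given);
    undefined values (no matches) are excluded from the averages.
    """
    times = mua.times
    results: dict[str, list[float]] = {"up": [], "down": []}
    skipped = {"up": 0, "down": 0}
    for label, intervals in (("up", seg.up_intervals), ("down", seg.down_intervals)):
        for start, end in intervals:
            sel = (times >= start) & (times < end)
            vals = mua.values[sel]
            if vals.size < max(min_bins, m + 2):
                skipped[label] += 1
                continue
            tol = r_abs if r_abs is not None else r_factor * float(vals.std())
            s = sample_entropy(vals, m=m, r_abs=tol)
            if np.isfinite(s):
                results[label].append(s)
            else:
                skipped[label] += 1
    for label in ("up", "down"):
        if not results[label]:
            raise ValueError(f"no usable {label} segments for SampEn")
    return EntropyMetrics(
        sampen_up=float(np.mean(results["up"])),
        sampen_down=float(np.mean(results["down"])),
        m=m,
        r_factor=r_factor,
        n_up_used=len(results["up"]),
        n_down_used=len(results["down"]),
        n_up_skipped=skipped["up"],
        n_down_skipped=skipped["down"],
    )
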