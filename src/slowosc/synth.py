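"""Synthetic multichannel LFP generator with known ground truth.

Emulates the statistical structure of deep-layer cortical recordings
under anesthesia: alternating Up/Down states with controllable mean
durations and cycle-frequency variability, an Up-state gamma-band
oscillation, a high-frequency (200-1500 Hz) "spiking" band driven by a
Poisson unit-event train, a 1/f background, and anteroposterior
traveling waves across a 16-electrode linear array.

Duration model
--------------
Up and Down durations are *shifted* gammas with a shared scale: each
state lasts at least ``state_floor_s`` (cortical Up/Down states do not
occur arbitrarily short), plus a gamma-distributed excess.  The cycle
period is then ``T = 2*floor + Gamma(K, theta)`` with ``K = k_up +
k_down``.  The shape ``K`` is tuned numerically (quadrature + root
finding) so the coefficient of variation of the per-cycle frequency
``1/T`` equals ``cycle_cv`` exactly in expectation; frequency-matched
presets additionally tune the mean cycle so that ``E[1/T]`` — the mean
per-cycle frequency, which is what the analysis measures — equals the
requested value (note ``E[1/T] != 1/E[T]`` for a variable cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.signal import fftconvolve

from .io import ChannelMeta, Recording

__all__ = [
    "GeneratorParams",
    "ArrayParams",
    "GroundTruth",
    "preset",
    "PRESET_NAMES",
    "sample_state_durations",
    "synthesize_channel",
    "synthesize_array",
]


@dataclass
class GeneratorParams:
    """Knobs of the single-channel generator.

    Durations are seconds, rates events/s, amplitudes arbitrary units
    (nominally microvolts).  ``cycle_cv`` is the coefficient of
    variation of the per-cycle frequency 1/(up+down).
    """

    mean_up_s: float = 0.5
    mean_down_s: float = 0.7
    cycle_cv: float = 0.4
    up_rate_hz: float = 2000.0
    down_rate_hz: float = 200.0
    gamma_peak_hz: float = 40.0
    gamma_amp: float = 60.0
    slow_amp: float = 300.0
    noise_1f_amp: float = 40.0
    rate: float = 20000.0
    seed: int = 0
    state_floor_s: float = 0.15

    def __post_init__(self) -> None:
        if self.mean_up_s <= 0 or self.mean_down_s <= 0:
            raise ValueError("state durations must be positive")
        if self.cycle_cv > 0 and (
            self.mean_up_s <= self.state_floor_s or self.mean_down_s <= self.state_floor_s
        ):
            raise ValueError(
                f"mean state durations must exceed the {self.state_floor_s} s floor"
            )
        if self.cycle_cv < 0:
            raise ValueError("cycle_cv must be >= 0")
        if self.up_rate_hz < 0 or self.down_rate_hz < 0:
            raise ValueError("event rates must be >= 0")
        if self.gamma_peak_hz >= self.rate / 2:
            raise ValueError("gamma_peak_hz must lie below Nyquist")

    @property
    def mean_cycle_s(self) -> float:
        return self.mean_up_s + self.mean_down_s

    @property
    def expected_so_freq_hz(self) -> float:
        """Expected mean per-cycle frequency E[1/T] under the duration model."""
        if self.cycle_cv == 0:
            return 1.0 / self.mean_cycle_s
        K = _solve_shape(self.mean_cycle_s, self.cycle_cv, 2 * self.state_floor_s)
        return _freq_moments(K, self.mean_cycle_s, 2 * self.state_floor_s)[1]


@dataclass
class ArrayParams:
    """Geometry and propagation parameters of the linear electrode array."""

    n_channels: int = 16
    spacing_mm: float = 0.1
    speed_mm_s: float = 17.5
    onset_jitter_s: float = 0.002
    origin: str = "first_channel"

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.speed_mm_s <= 0:
            raise ValueError("propagation speed must be positive")
        if self.origin not in ("first_channel", "last_channel"):
            raise ValueError("origin must be 'first_channel' or 'last_channel'")

    @property
    def positions_mm(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.spacing_mm


@dataclass
class GroundTruth:
    """Exact description of a generated recording, for use as a test oracle."""

    #: per-sample Up labels of the reference channel (bool array)
    state_labels: np.ndarray
    #: (n_cycles, 3) array of (down_start, up_start, up_end) in seconds
    cycle_table: np.ndarray
    params: GeneratorParams
    array_params: ArrayParams | None = None
    #: (n_waves, n_channels) true Up-onset time per wave per channel (s)
    channel_onsets: np.ndarray | None = None
    #: (n_waves, n_channels) onset lag of each channel relative to the wave mean (s)
    true_lags: np.ndarray | None = None

    @property
    def up_durations(self) -> np.ndarray:
        return self.cycle_table[:, 2] - self.cycle_table[:, 1]

    @property
    def down_durations(self) -> np.ndarray:
        return self.cycle_table[:, 1] - self.cycle_table[:, 0]


# Pooled group means printed for the two strains at the two ages:
# SO frequency (Hz), frequency CV, and (at 5 months) Up/Down durations (s).
_POOLED = {
    "SAMR1_5M": {"freq": 1.02, "cv": 0.40, "down": 0.71, "up": 0.49, "gamma": 40.0},
    "SAMP8_5M": {"freq": 0.72, "cv": 0.53, "down": 1.10, "up": 0.61, "gamma": 30.0},
    "SAMR1_7M": {"freq": 0.91, "cv": 0.48, "down": None, "up": None, "gamma": 35.0},
    "SAMP8_7M": {"freq": 0.77, "cv": 0.61, "down": None, "up": None, "gamma": 30.0},
}

PRESET_NAMES = tuple(_POOLED)

#: firing-rate drives per strain: the accelerated-senescence strain shows
#: lower Down-state background firing than its control.
_RATES = {"SAMR1": (2000.0, 300.0), "SAMP8": (1800.0, 150.0)}


def preset(name: str, matching: str = "duration_matched", **overrides) -> GeneratorParams:
    """Generator parameters matching a strain x age group's pooled means.

    Parameters
    ----------
    name : {"SAMR1_5M", "SAMP8_5M", "SAMR1_7M", "SAMP8_7M"}
    matching : {"duration_matched", "frequency_matched"}
        The pooled duration means and the pooled frequency mean printed
        for a group are mutually inconsistent under f = 1/(up+down)
        (Jensen's inequality plus across-area averaging), so one of the
        two is matched exactly:

        - ``duration_matched`` sets ``mean_up_s``/``mean_down_s`` to the
          group's pooled duration means (5-month values; 7-month
          durations, which were not reported numerically, are derived
          from the 7-month frequency keeping the strain's Up:Down ratio).
        - ``frequency_matched`` calibrates the cycle-period distribution
          so the *expected mean per-cycle frequency* E[1/T] equals the
          group's pooled frequency, keeping the strain's Up:Down ratio.

    Any :class:`GeneratorParams` field may be overridden by keyword.
    """
    if name not in _POOLED:
        raise KeyError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    if matching not in ("duration_matched", "frequency_matched"):
        raise ValueError("matching must be 'duration_matched' or 'frequency_matched'")
    row = _POOLED[name]
    strain = name.split("_")[0]
    cv = row["cv"]
    # Up:Down ratio from the strain's printed 5-month durations
    ref = _POOLED[f"{strain}_5M"]
    up_frac = ref["up"] / (ref["up"] + ref["down"])

    floor = float(overrides.get("state_floor_s", GeneratorParams.state_floor_s))
    if matching == "duration_matched" and row["down"] is not None:
        mean_down, mean_up = row["down"], row["up"]
    else:
        # tune the mean cycle so the expected mean per-cycle frequency E[1/T]
        # equals the printed pooled frequency at this CV
        total = _solve_mean_cycle(row["freq"], cv, 2 * floor)
        mean_up = up_frac * total
        mean_down = total - mean_up

    up_rate, down_rate = _RATES[strain]
    params = GeneratorParams(
        mean_up_s=mean_up,
        mean_down_s=mean_down,
        cycle_cv=cv,
        up_rate_hz=up_rate,
        down_rate_hz=down_rate,
        gamma_peak_hz=row["gamma"],
    )
    return replace(params, **overrides) if overrides else params


_QUAD_NODES, _QUAD_WEIGHTS = np.polynomial.legendre.leggauss(400)
_QUAD_U = 0.5 * (_QUAD_NODES + 1.0)  # probability-space nodes on (0, 1)
_QUAD_W = 0.5 * _QUAD_WEIGHTS


@lru_cache(maxsize=1024)
def _freq_moments(K: float, mean_cycle: float, floor: float) -> tuple[float, float]:
    """(CV, mean) of the per-cycle frequency 1/T, T = floor + Gamma(K, theta).

    Moments are Gauss-Legendre quadrature in probability space
    (E[f(G)] = int_0^1 f(ppf(u)) du), which is fast and accurate here
    because 1/(floor + g) is bounded and smooth.
    """
    theta = (mean_cycle - floor) / K
    g = sps.gamma.ppf(_QUAD_U, K, scale=theta)
    inv = 1.0 / (floor + g)
    e1 = float(np.sum(_QUAD_W * inv))
    e2 = float(np.sum(_QUAD_W * inv**2))
    var = max(e2 - e1**2, 0.0)
    return float(np.sqrt(var) / e1), e1


@lru_cache(maxsize=256)
def _solve_shape(mean_cycle: float, cv: float, floor: float) -> float:
    """Total gamma shape K giving frequency CV == cv at fixed mean cycle.

    CV(K) rises from ~0 at tiny K to a maximum near K ~ 0.5 and decays
    to 0 as K grows; the solution is taken on the decreasing
    (less-skewed) branch.  Raises if ``cv`` exceeds the attainable
    maximum for this floor/mean combination.
    """
    if mean_cycle <= floor:
        raise ValueError("mean cycle must exceed the total state floor")
    grid = np.geomspace(0.2, 4000.0, 28)
    cvs = np.array([_freq_moments(K, mean_cycle, floor)[0] for K in grid])
    i_peak = int(np.argmax(cvs))
    if cv > cvs[i_peak]:
        raise ValueError(
            f"cycle_cv = {cv} infeasible: maximum attainable CV is {cvs[i_peak]:.3f} "
            f"for mean cycle {mean_cycle:.3f} s with a {floor:.2f} s total floor"
        )
    lo, hi = grid[i_peak], grid[-1]
    return float(
        brentq(lambda K: _freq_moments(K, mean_cycle, floor)[0] - cv, lo, hi, xtol=1e-6)
    )


@lru_cache(maxsize=64)
def _solve_mean_cycle(freq: float, cv: float, floor: float) -> float:
    """Mean cycle such that E[1/T] == freq with the shape retuned to keep CV."""

    def err(mu: float) -> float:
        K = _solve_shape(mu, cv, floor)
        return _freq_moments(K, mu, floor)[1] - freq

    # the requested CV is unattainable for mean cycles too close to the
    # floor; scan for a feasible bracket with a sign change
    hi = 4.0 / freq
    lo = None
    for mu in np.geomspace(floor * 1.05, hi, 40):
        try:
            e = err(float(mu))
        except ValueError:
            continue
        if e > 0:
            lo = float(mu)
        else:
            if lo is None:
                raise ValueError(
                    f"no mean cycle attains frequency {freq} Hz at cv {cv} "
                    f"with a {floor:.2f} s total floor"
                )
            hi = float(mu)
            break
    if lo is None:
        raise ValueError(f"frequency {freq} Hz unattainably low for cv {cv}")
    return float(brentq(err, lo, hi, xtol=1e-8))


def _gamma_shapes(params: GeneratorParams) -> tuple[float, float, float]:
    """Shared-scale gamma parameters (k_up, k_down, theta) of the excess
    durations above the per-state floor."""
    floor = params.state_floor_s
    K = _solve_shape(params.mean_cycle_s, params.cycle_cv, 2 * floor)
    theta = (params.mean_cycle_s - 2 * floor) / K
    return (
        (params.mean_up_s - floor) / theta,
        (params.mean_down_s - floor) / theta,
        theta,
    )


def sample_state_durations(
    params: GeneratorParams, n_cycles: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_cycles`` (up, down) duration pairs from the gamma model.

    Returns ``(up_durations, down_durations)`` in seconds.  With
    ``cycle_cv == 0`` every cycle is exactly the mean durations.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.cycle_cv == 0:
        return (
            np.full(n_cycles, params.mean_up_s),
            np.full(n_cycles, params.mean_down_s),
        )
    k_up, k_down, theta = _gamma_shapes(params)
    floor = params.state_floor_s
    up = floor + rng.gamma(k_up, theta, size=n_cycles)
    down = floor + rng.gamma(k_down, theta, size=n_cycles)
    return up, down


def _one_over_f_noise(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    f[0] = f[1]  # avoid DC blow-up
    spec *= 1.0 / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _event_kernel(rate: float) -> np.ndarray:
    """1 ms biphasic unit-event waveform (one sine cycle, Hann-windowed)."""
    n = max(int(round(0.001 * rate)), 2)
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.hanning(n)


def _cycle_skeleton(
    params: GeneratorParams, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw cycles until ``duration_s`` is covered; return (n, 3) cycle table.

    Each row is (down_start, up_start, up_end) in seconds; the recording
    starts at the beginning of a Down state.
    """
    n_guess = int(duration_s / params.mean_cycle_s * 1.5) + 20
    up, down = sample_state_durations(params, n_guess, rng)
    while (up + down).sum() < duration_s + params.mean_cycle_s:
        u2, d2 = sample_state_durations(params, n_guess, rng)
        up = np.concatenate([up, u2])
        down = np.concatenate([down, d2])
    cycle_end = np.cumsum(up + down)
    down_start = cycle_end - up - down
    up_start = down_start + down
    keep = down_start < duration_s
    return np.column_stack([down_start[keep], up_start[keep], cycle_end[keep]])


def _labels_from_cycles(cycles: np.ndarray, n: int, rate: float) -> np.ndarray:
    """Per-sample Up labels (half-open [up_start, up_end) intervals)."""
    labels = np.zeros(n, dtype=bool)
    for _, u0, u1 in cycles:
        i0 = max(int(np.ceil(u0 * rate)), 0)
        i1 = min(int(np.ceil(u1 * rate)), n)
        if i1 > i0:
            labels[i0:i1] = True
    return labels


def _render_channel(
    params: GeneratorParams,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one channel's LFP from per-sample Up labels."""
    n = labels.size
    rate = params.rate
    sig = params.noise_1f_amp * _one_over_f_noise(n, rate, rng)

    # smoothed Up envelope (25 ms edges): drives the slow deflection and gamma
    env = gaussian_filter1d(labels.astype(float), sigma=0.025 * rate)
    # deep-layer convention: Up states deflect negative
    sig -= params.slow_amp * env

    if params.gamma_amp > 0:
        t = np.arange(n) / rate
        phase = rng.uniform(0, 2 * np.pi)
        sig += params.gamma_amp * env * np.sin(2 * np.pi * params.gamma_peak_hz * t + phase)

    # Poisson unit events convolved with a 1 ms biphasic kernel
    lam = np.where(labels, params.up_rate_hz, params.down_rate_hz) / rate
    counts = rng.poisson(lam).astype(float)
    if counts.any():
        sig += 25.0 * fftconvolve(counts, _event_kernel(rate), mode="same")
    return sig.astype(np.float32)


def synthesize_channel(
    params: GeneratorParams, duration_s: float
) -> tuple[Recording, GroundTruth]:
    """Generate a single-channel recording plus its ground truth."""
    if duration_s < 10 * params.mean_cycle_s:
        raise ValueError(
            f"duration {duration_s} s too short; need >= 10 mean cycles "
            f"({10 * params.mean_cycle_s:.2f} s)"
        )
    rng = np.random.default_rng(params.seed)
    cycles = _cycle_skeleton(params, duration_s, rng)
    n = int(round(duration_s * params.rate))
    labels = _labels_from_cycles(cycles, n, params.rate)
    sig = _render_channel(params, labels, rng)
    rec = Recording(
        samples=sig[np.newaxis, :],
        rate=params.rate,
        channels=[ChannelMeta(label="sim0", area="synthetic")],
        arbitrary_units=True,
    )
    truth = GroundTruth(state_labels=labels, cycle_table=cycles, params=params)
    return rec, truth


def synthesize_array(
    params: GeneratorParams, arr: ArrayParams, duration_s: float
) -> tuple[Recording, GroundTruth]:
    """Generate a linear-array recording with traveling Up-state onsets.

    All channels share one cycle skeleton; channel *c*'s Up intervals
    are delayed by ``position_c / speed_mm_s`` (reversed when the wave
    originates at the last channel) plus per-wave Gaussian jitter.
    """
    if duration_s < 10 * params.mean_cycle_s:
        raise ValueError("duration too short; need >= 10 mean cycles")
    seeds = np.random.SeedSequence(params.seed).spawn(arr.n_channels + 2)
    rng_skel = np.random.default_rng(seeds[0])
    rng_jit = np.random.default_rng(seeds[1])

    cycles = _cycle_skeleton(params, duration_s, rng_skel)
    n_waves = cycles.shape[0]
    pos = arr.positions_mm
    delays = pos / arr.speed_mm_s
    if arr.origin == "last_channel":
        delays = delays[::-1].copy()
    jitter = (
        rng_jit.normal(0.0, arr.onset_jitter_s, size=(n_waves, arr.n_channels))
        if arr.onset_jitter_s > 0
        else np.zeros((n_waves, arr.n_channels))
    )
    onsets = cycles[:, 1][:, None] + delays[None, :] + jitter

    n = int(round(duration_s * params.rate))
    chans = []
    metas = []
    ref_labels = None
    for c in range(arr.n_channels):
        shift_c = onsets[:, c] - cycles[:, 1]
        cyc_c = cycles + shift_c[:, None]  # shift whole cycle, durations preserved
        labels_c = _labels_from_cycles(cyc_c, n, params.rate)
        if c == 0:
            ref_labels = labels_c
        rng_c = np.random.default_rng(seeds[c + 2])
        chans.append(_render_channel(params, labels_c, rng_c))
        metas.append(
            ChannelMeta(label=f"sim{c}", area="synthetic", position_mm=float(pos[c]))
        )
    rec = Recording(
        samples=np.vstack(chans), rate=params.rate, channels=metas, arbitrary_units=True
    )
    truth = GroundTruth(
        state_labels=ref_labels,
        cycle_table=cycles,
        params=params,
        array_params=arr,
        channel_onsets=onsets,
        true_lags=onsets - onsets.mean(axis=1, keepdims=True),
    )
    return rec, truth
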