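# Methods

This note documents the models and procedures `slowosc` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that
matter when reproducing results.

## Up/Down state detection

An Up state in deep-layer cortical LFP shows three simultaneous
signatures: a slow voltage deflection (negative, by the deep-layer
convention), a rise in gamma-band activity, and population firing.
Detection extracts each as a time series on a common 5 ms grid:

1. **SO envelope** — the LFP low-pass filtered at 2 Hz (4th-order
   Butterworth, zero-phase `sosfiltfilt`), averaged per 5 ms bin. The
   polarity of the slow deflection varies with layer and reference, so
   the series is sign-oriented by its correlation with a broadband
   high-frequency activity trace; the whole chain is therefore
   polarity- and gain-agnostic (tested by sign-flip/rescale
   invariance).
2. **Gamma variance envelope** — the LFP band-passed to 20–80 Hz
   (zero-phase), power within each 5 ms bin, smoothed by a 50 ms moving
   average.
3. **logMUA** — see below.

Each series is z-scored and the three are combined by projecting onto
the first principal component of their 3×3 correlation matrix, with
the sign chosen so the combined series correlates positively with
logMUA. Because the three features occupy disjoint frequency bands,
the PCA weighting downweights any band-limited artifact or degenerate
feature (a constant feature gets weight 0 with a warning). PCA is
computed per channel, not pooled across recordings, which makes the
combination robust to gain differences between electrodes.

The combined series is thresholded at the trough between the two modes
of its smoothed histogram. When no clean trough exists, the fallback is
the midpoint of a 2-means split — but only if the split is a genuine
bimodality: we require Ashman's D (centre separation divided by the
root-sum-of-squares of the cluster SDs) to be at least 2.0. A 2-means
split of *unimodal* data, Gaussian or skewed, measures D ≲ 1.95 (and a
silhouette of ~0.5, which is why a silhouette criterion cannot reject a
stationary null), while genuinely state-alternating series measure
D ≥ 2.2; below the cutoff the model raises "no state alternation
detected".

Cleanup: Down gaps shorter than `merge_gap_s` (50 ms) between Up runs
are merged; runs shorter than `min_state_s` (100 ms) are absorbed into
their flanking state, shortest first; partial states touching the
recording edges are dropped. A cycle is a complete Down followed by its
terminating Up (the Down-to-Up transition is the anchor). Intervals are
half-open `[start, end)` in seconds; sample indices are 0-based.

**SO metrics.** Per-cycle frequency is `f_i = 1/(Up_i + Down_i)`; the SO
frequency is the arithmetic mean of the `f_i`, and the cycle CV is
`SD(f_i)/mean(f_i)` with the sample (n−1) SD. Note the mean per-cycle
frequency is *not* the inverse of the mean cycle length (Jensen's
inequality); everything in this package consistently uses the mean of
per-cycle frequencies.

## logMUA

Multi-unit activity is estimated from spectral power at 200–1500 Hz,
where Fourier component density is proportional to the spiking of the
local population. The signal is band-passed to 200–1500 Hz (zero-phase)
first — a 5 ms window has only 200 Hz resolution, so without the filter
a large low-frequency component would leak into the band — then the
mean periodogram power over the band is computed in non-overlapping
5 ms rectangular windows, floored at 10⁻¹² × the series median (Down
states in synthetic data can be nearly silent), and natural-log
transformed.

Absolute firing rates are mean logMUA over Up and over Down intervals
(bins assigned by bin centre). The relative firing rate averages the
logMUA waveform across all Down-to-Up transitions over ±0.5 s,
subtracts the mean of the pre-transition portion, and takes the maximum
of the post-transition portion; the order (average, then maximum)
matters and is pinned by a test in which asynchronous per-transition
peaks make the two orders differ.

## Traveling waves

Per-channel Up-onset times are grouped into waves by a recursive
windowing pass: the initial window is half the median inter-onset
interval; each iteration assigns every onset to the nearest provisional
wave time (at most one onset per channel per wave, closest wins),
recomputes wave times as member means, and shrinks the window by 0.75
until the assignment is stable or the window falls below 20 ms.
Time-compatible partial waves with disjoint channel sets are then
merged, and waves covering fewer than 10 of 16 electrodes are rejected.
Lags are onsets minus the wave's mean onset (they sum to zero per
wave).

Lag vectors are clustered with k-means, k = min(5, n_waves), 50
restarts, fixed seed; missing channels are imputed by the per-channel
mean and refined once by the assigned cluster's mean. Each cluster's
speed is the distance between the electrodes with extreme mean lags
divided by their lag difference; the recording's speed is the mean over
clusters weighted by the proportion of waves each contains. Clusters
with zero lag spread have undefined speed and are excluded with weight
renormalization. Direction is reported only as the sign of the
lag-versus-position regression slope; speed is unsigned.

## Spectra and power excess

Per-state PSDs use Welch's method with Hann-tapered, 50 %-overlapped
windows of 5000 samples at the native rate (250 ms / 4 Hz bins at
20 kHz), drawing windows only from within same-state segments — no
cross-segment concatenation, so segments shorter than one window are
skipped (short-Up exclusion is the documented consequence). Detrending
is off so Parseval holds: the PSD integral matches the signal variance
within 1 % on white noise. When analyzing recordings at other rates,
`window_samples ≈ rate/4` keeps the 4 Hz bin width.

The aperiodic background is fitted as `A/f^α` by linear regression of
log power on log frequency over 5–100 Hz, with one robustness pass
excluding bins more than 2 SD *above* the fit (oscillatory peaks push
power up, not down). The exponent is free; an exact-1/f fit is the
special case α = 1. The **power excess** is `PSD(f)/fit(f)`; its peak is
searched in 10–90 Hz (the beta–gamma range of interest). A spectrally
exact `A/f` input yields a flat excess of 1; the result is then flagged
`flat` and the peak pinned at the band's lower edge rather than
reporting an argmax of numerical noise.

## Sample entropy

SampEn(m, r, N) = −ln(A/B), where B counts pairs of length-m templates
within Chebyshev distance r and A the pairs still within r at length
m+1, self-matches excluded; both counts run over the first N−m
templates so every template has an (m+1)-extension. Defaults m = 2 and
r = 0.25 × SD follow the physiological-complexity convention; r is
scaled by each segment's own SD (making the measure affine-invariant),
with an absolute-r mode available. SampEn is computed per state
segment on its logMUA bins (segments with fewer than 10 bins ≈ 50 ms
are skipped and counted), undefined values (zero matches) are excluded,
and the remaining values are averaged per state class. The
implementation is verified against an exhaustive brute-force pair
counter on all short fixtures.

## Statistics

Group contrasts use the classic pooled-variance independent-samples
Student t-test (Welch available by flag); correlations are Pearson with
the t-transform p-value (n−2 df). No multiple-testing correction is
applied; reports print raw p-values. Pooled-area comparisons enter each
per-recording area value as an independent observation, which
overstates degrees of freedom when several areas come from one animal —
a deliberate, documented simplification.

## Synthetic LFP generator

The generator emulates the statistical structure the analysis assumes,
with exact ground truth for testing:

- **State durations.** Up and Down durations are shifted gammas with a
  shared scale: `duration = floor + Gamma(k, θ)`, floor 0.15 s per
  state. The floor reflects that cortical states do not occur
  arbitrarily short, and guarantees no true state is clipped by the
  detector's 0.1 s minimum. The cycle period is then
  `T = 0.3 + Gamma(K, θ)`; the shape K is solved numerically
  (Gauss–Legendre quadrature in probability space plus Brent root
  finding, on the decreasing branch of CV(K)) so that the CV of the
  per-cycle frequency `1/T` equals `cycle_cv` exactly in expectation.
  Requested CVs above the attainable maximum raise a parameter error.
- **Presets** encode the pooled phenotypes of the two mouse strains at
  two ages. Printed duration means and printed frequency means are
  mutually inconsistent under `f = 1/(Up+Down)` (Jensen plus
  across-area averaging), so each preset comes in two flavours:
  `duration_matched` fixes the state-duration means (5-month values;
  the 7-month durations, never reported numerically, are derived from
  the 7-month frequency keeping the strain's Up:Down ratio), and
  `frequency_matched` tunes the cycle distribution so `E[1/T]` — the
  quantity the pipeline measures — equals the group's frequency.
- **Signal.** Each channel is the sum of (i) 1/f-power background noise
  (spectral shaping of white noise, exponent 1), (ii) a negative slow
  deflection following the Up indicator smoothed with a 25 ms Gaussian,
  (iii) an Up-gated gamma sinusoid at `gamma_peak_hz` with random
  phase, and (iv) a Poisson unit-event train (rate `up_rate_hz` during
  Up, `down_rate_hz` > 0 during Down, so Down-state firing metrics are
  non-degenerate) convolved with a 1 ms biphasic kernel. Default
  amplitudes (slow 300, gamma 60, noise 40, in arbitrary
  microvolt-scale units) give the detector realistic, not trivial,
  feature contrast.
- **Arrays.** All 16 channels (100 µm spacing) share one cycle
  skeleton; channel c's cycles are delayed by `position_c / speed` plus
  per-wave Gaussian onset jitter (default 2 ms). Channel noise and
  event trains are independent streams spawned from one seed, so
  identical parameters and seed reproduce the recording bit-exactly.

What the generator does **not** emulate: biophysical Up-state
generation mechanisms, anesthesia-depth drift, electrode drift and
artifacts, inter-areal coupling beyond shared cycles, spike waveform
diversity, and realistic absolute amplitudes (synthetic recordings are
flagged `arbitrary_units`). Tests passing on this generator show the
*analysis chain* is correct and unbiased under its assumptions; they do
not certify performance on recordings whose noise violates them.

## Problem sizes

Recovery tests and the acceptance script use 300 s single-channel
simulations at 10 kHz (5 seeds per condition), 240 s 16-channel arrays
at 5 kHz, and 120 s runs for spectral-peak recovery, with Welch windows
of `rate/4` samples to keep 4 Hz resolution. These sizes give ~150–300
cycles per run, enough that sample fluctuations of the heavy-tailed
per-cycle frequency stay within the documented tolerances.

## Known limitations

- The histogram-trough threshold has no hysteresis; very noisy combined
  series produce brief spurious runs that the min-duration cleanup must
  absorb.
- The wave "recollection" merge is one consistent reading of an
  under-specified step (merging disjoint, time-compatible partial
  waves); it is isolated in a single function.
- Sample CV of the per-cycle frequency is biased slightly low in short
  recordings (heavy-tailed statistic); 300 s runs keep the bias within
  ±0.02.
- SampEn absolute values depend on the logMUA bin noise level; only
  within-design comparisons (Up vs Down, group vs group) are
  meaningful.
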