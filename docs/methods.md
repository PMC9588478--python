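# Methods

## The problem

Power spectra of electrophysiological recordings (EEG, MEG, LFP) mix two
components: an aperiodic part whose density follows a power law
`P(f) ∝ 1/f^β`, and periodic peaks riding on it, produced by neural
oscillations. Estimating the 1/f exponent β — used, among other things,
as a proxy for cortical excitation–inhibition balance — requires
separating the two. This package implements the two standard separation
approaches and a simulation harness that measures exactly when and how
they fail, against spectra whose ground truth is known by construction.

## Ground-truth simulator (`aperiodic.sim`)

A one-sided Fourier **power** spectrum is constructed on the rfft grid
of the requested series,

    S(f) = C · f^(−β) · Π_j [1 + A_j · exp(−(f − f_j)² / (2 σ_j²))],

uniform-random phases are attached, and the inverse FFT produces the
series. Because the construction is exact, the boxcar periodogram of the
noiseless series equals `S(f)` bin for bin (relative error ~1e−13, a
tested invariant), and every downstream estimate can be scored against
known truth.

Choices that matter:

* **Peak convention.** Peaks multiply the aperiodic power, so `A` is a
  dimensionless relative height (`log10(1 + A)` decades at the center).
  Published toolboxes differ here (some add peaks in log power); the
  multiplicative form keeps peak size interpretable against the local
  aperiodic level.
* **Normalization.** `C` is set so the noiseless series has unit
  variance; the additive white-noise scale is therefore an SNR-like
  number.
* **DC and the low-frequency bound.** The DC bin is zero, and the power
  law is truncated below `f_construct_min` (default 0.3 Hz). An
  unbounded `f^(−β)` puts most of the variance into fluctuations slower
  than anything an acquisition system passes (the emulated recording
  systems highpass at 0.3–1 Hz), and the spectral leakage of that
  sub-bin power through 1 s Hann segments steepens a β = 2 spectrum's
  1–10 Hz fit to ≈ 2.10. With the bound, the same fit reads ≈ 1.97.
  0.3 Hz is the lowest hardware cutoff among the emulated systems.
* **Randomness.** One seeded generator draws phases first, then noise,
  so enabling noise does not change the fractal realization.
* **Transients.** Sawtooth transients emulate the spike-wave discharges
  of absence seizures. The waveform rises through zero at the interval
  start; `width` is the fraction of the period spent rising. The ideal
  ramp (`width = 1`) has harmonic amplitudes ∝ 1/k; real discharges have
  finite slew, and the seizure scenarios use `width = 0.9`, whose
  harmonics fall off roughly one order faster (see *Scenarios* below for
  why this distinction is load-bearing).
* **Highpass emulation.** A zero-phase 4th-order Butterworth, recorded
  in provenance so the stopband shape is reproducible.

What the generator does **not** emulate: multichannel/spatial structure,
line noise, nonstationarity other than the transient intervals,
time-varying β, or a spectral knee (the knee exists only as a fitting
option). Passing tests therefore demonstrate estimator behavior under
stationary, single-channel, Gaussian-phase conditions — the regime in
which the published failure modes were themselves derived — and say
nothing about, e.g., artifact rejection on real recordings.

## PSD estimation (`aperiodic.psd`)

Welch with Hann windows, 50% overlap, per-segment mean removal,
one-sided density, incomplete last segment dropped. Two configurations
are used throughout: 1 s segments (1 Hz resolution; smooth input for the
peak parameterizer) and 4 s segments (0.25 Hz; inside the resampling
separator). The density integrates to the series variance up to
windowing bias (tested at 5% for ≥ 60 segments).

## Spectral parameterizer (`aperiodic.specparam`)

An iterative Gaussian-peaks-over-aperiodic model in log10 power:

1. **Robust initial line.** Ordinary least squares in log–log space,
   then a refit restricted to bins whose positive residual is below the
   2.5th percentile of the clipped positive residuals. Since roughly
   half the residuals are negative (and clip to zero), this keeps the
   at-or-below-line bins and discounts peaks.
2. **Iterative extraction.** The largest flattened-spectrum maximum
   exceeding both the absolute threshold and `peak_threshold` (default
   2) standard deviations is fitted by a bounded Gaussian (center within
   ±2 initial σ, width within the configured limits interpreted as
   bounds on 2σ) on a ±3σ window and subtracted. The SD threshold is
   recomputed from the peak-removed spectrum after every extraction.
   Troughs are never fitted. Ties in the maximum resolve to the lowest
   frequency. A hard cap of 100 iterations guards against degenerate
   spectra.
3. **Edge rule.** A fitted Gaussian whose center lies within one σ of a
   fit-range border is discarded: partial peaks are not modeled, and
   their unmodeled power is what corrupts the aperiodic fit when an
   oscillation crosses a border — the central border-crossing failure
   mode, which disappears if half-peaks are allowed into the model.
4. **Joint refit.** All accepted Gaussians are refit simultaneously,
   unless more than 15 were extracted (e.g. a harmonic comb), in which
   case the joint problem has nearly as many parameters as data points
   and the iterative estimates are kept (flagged on the model).
5. **Final aperiodic fit.** Plain least squares on the peak-subtracted
   spectrum; this is the reported offset and exponent. With
   `max_n_peaks = 0` the reported exponent is therefore the plain
   log–log line — also what the sliding-window plateau detector uses.

The knee form, used only on request, is
`log10 P = offset − log10(knee + f^χ)` with the exponent reported as χ.

Peak bandwidth is serialized as `2·σ²` (a variance-like quantity, not a
width in Hz) following the convention of the reports this package
reproduces; the Gaussian σ is kept alongside and the width limits
constrain `2σ`. The ambiguity is noted here deliberately.

## Irregular-resampling separation (`aperiodic.irasa`)

The series is resampled by each factor `h` in the h-set (default 1.1 to
1.9 in steps of 0.05 — 17 factors) and by `1/h`, with the resampled
series *declared at the original sampling rate*: upsampling compresses
spectral features to `f/h`, downsampling displaces them to `f·h`, while
a fractal spectrum maps to `h^(∓β)·f^(−β)` whose per-pair geometric mean
restores `f^(−β)` exactly. The per-bin median over the 17 geometric
means is the aperiodic component; the original PSD minus it is the
periodic component (the decomposition reconstructs the input exactly,
by construction). The exponent is a least-squares log–log line over the
fitting range.

Numerics: factors are approximated by rationals to a relative 1e−4 for
polyphase resampling (anti-aliasing at the lower Nyquist of each pair);
up/downsampled PSDs use the same segment duration in seconds and are
interpolated onto the original Welch grid in log power, which preserves
power-law straightness.

**Evaluated-range safety.** A nominal fitting range `(f_lo, f_hi)` draws
on original-spectrum content over `(f_lo/h_max, f_hi·h_max)`, and the
strongest downsampling lowers the usable Nyquist to `f_s/(2·h_max)`.
With `strict=True` (default) the separator refuses: an upper fitting
border beyond the resampled Nyquist, an evaluated range extending beyond
it, or an evaluated range dipping into a known highpass stopband — each
error names the violated bound. `strict=False` runs anyway, because
demonstrating exactly these violations is how the failure-mode scenarios
work. Fitting 1–100 Hz at a 256 Hz sampling rate, for instance, yields
β ≈ 2.24 on a β = 1.8 truth: beyond 67 Hz the most-downsampled spectrum
contains only anti-aliasing stopband residue, and the median collapses
into it.

## Diagnostics (`aperiodic.diagnostics`)

* **Plateau onset.** The aperiodic-only exponent is fitted on a sliding
  window (default 50 Hz wide, 1 Hz steps); the onset is the first window
  start whose exponent drops below 0.05. First hit, no persistence
  requirement — the scan stops there unless the full trace is requested.
  On a single estimated PSD this is a first-passage statistic and
  scatters by tens of Hz; code that needs a stable quantity averages
  detected onsets over realizations.
* **Noise calibration.** `calibrate_noise_for_plateau` inverts the
  detector by monotone bisection on the noise scale, targeting the
  *mean* detected onset over (default) 10 realizations, each detected on
  its own single-realization PSD — the statistic matching how the
  detector is actually used. Calibrating instead on an averaged PSD
  suppresses the first-passage scatter and lands on ≈ 40% more noise for
  the same nominal onset. The plateau scenarios raise the calibration
  ensemble to 30 realizations, putting the mean-onset standard error
  near 2 Hz so the calibrated scale no longer depends on the seed choice
  at any level that moves the downstream exponents.
* **Logarithmic peak width.** `Δf_log = log10(f2/f1)` with peak bounds
  from the first/last bins whose *relative* deviation from a known
  aperiodic truth exceeds 0.001 (the relative convention is the only
  scale-free reading; an absolute-units threshold would change the
  numeric Δf_log scale, so published Δf_log values under other
  conventions differ by roughly a factor 2 from this package's).
* **Straight-line exponent.** The slope between two log–log PSD points —
  the naive reference estimator; exact on exact power laws.
* **Border sweeps.** One exponent estimate per lower fitting border
  (integer Hz, inclusive), upper border fixed; per-border failures yield
  NaN rows rather than aborting.

## Challenge scenarios (`aperiodic.challenges`)

Each scenario fixes the simulation conditions and reports
(seed, method, condition, estimate, truth, error) rows; defaults run 10
seeds. Parameters the source experiments did not print were fixed once
at values a practitioner would call realistic:

* **plateau_bias** — β = 2, 180 s at 2400 Hz, noise calibrated to a
  100 Hz onset; aperiodic-only fits over 1–10/1–50/1–100/1–200 Hz show
  the plateau dragging the exponent from ≈ 1.97 to ≈ 0.70.
* **border_sweep** — peaks at 5/15/35 Hz with relative heights (5, 4, 3)
  and σ = (0.4, 0.5, 1.0) Hz: heights of 0.6–0.8 decades, and widths
  narrow on the log axis (σ/cf ≤ 0.08) so the default h-set separates
  the resampled copies — the regime in which the resampling separator is
  supposed to work, leaving the border-crossing failure to the
  parameterizer alone. Ensemble error curves: parameterizer errors up to
  ≈ 0.35 with local maxima at the peak centers; separator error < 0.1
  for every border.
* **delta_power** — β = 1.5 with a 2 Hz delta peak (σ = 1.2 Hz) crossing
  the 1 Hz border plus fixed peaks at 12/18/27/50 Hz; scaling only the
  delta amplitude (0×, 1×, 2×) moves the estimate monotonically while
  the truth is constant.
* **sawtooth** — β = 1.8, 60 s at 256 Hz (matched to the absence-seizure
  recording it emulates), 3 Hz sawtooth of amplitude 3 and width 0.9
  during 20–40 s. Both methods inflate during the transient
  (≈ 1.81 → 2.0). The width matters: an ideal ramp's harmonic comb has a
  log–log power envelope of exactly −2, which *deflates* the fits
  instead; the finite-slew waveform is both the realistic morphology and
  the one that reproduces the documented inflation.
* **highpass_hmax / plateau_hmax** — a 1 Hz highpass stopband (resp. a
  calibrated noise plateau) enters the evaluated range as h_max grows
  through {2, 8, 15} (nine factors per set; set size is otherwise
  immaterial): the 2–30 Hz fit is accurate only at h_max = 2 and
  degrades monotonically.
* **peak_width_hmax** — peaks at 30 and 300 Hz with equal logarithmic
  widths (absolute widths differing tenfold). At Δf_log = 0.15 the
  default-size factors remove them (contamination < 1% of peak power);
  at Δf_log = 0.4 removal fails at h_max = 2 (≈ 34%) and succeeds at
  h_max = 8 (≈ 1.4%). Contamination is the maximum excess of the
  separated aperiodic component over the known truth within the peak
  band, relative to the peak's density at its center.
* **overlap_failure** — the sawtooth scenario plus two strongly
  overlapping peaks at 10 and 25 Hz (σ = 3.5 and 6 Hz), separated with
  the deliberately out-of-range 1–100 Hz fit at 256 Hz (`strict=False`)
  that the published experiment used: 2.42 without the overlapping
  peaks, ≈ 2.98 with them, against a truth of 1.8.

## Problem sizes and runtimes

Scenario defaults follow the study conditions: 180 s at 2400 Hz (or 60 s
at 256 Hz for the seizure-matched scenarios), 10 realization seeds. The
fractal-invariance property (per-bin periodic residual < 5% of aperiodic
power) is tested on 1800 s records: the residual is pure chi-square
estimation scatter of the Welch estimate (mean ≈ 1% at that length), so
its per-bin maximum is set by record length, not by the separation.

## Known limitations

* The parameterizer is a from-scratch implementation of the published
  algorithm's description, not a bit-for-bit port of any toolbox;
  iterative peak fits are refined per-iteration rather than
  guess-and-joint-fit only, which makes single-peak recovery tighter but
  can differ in overlapping-peak decompositions.
* Tall multiplicative peaks saturate in log power and legitimately
  decompose into several Gaussians; peak *counts* are only meaningful
  for moderate amplitudes.
* The plateau detector's first-hit rule makes single-PSD onsets noisy by
  design; all calibrated results quote ensemble means.
* Residual scatter of the calibrated noise scale propagates into the
  plateau-bias exponents at the ±0.02 level (30-realization
  calibration); the 1–200 Hz range, where the plateau dominates the fit,
  is the most sensitive.
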