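# aperiodic

Separating neural oscillations from aperiodic 1/f activity — and
measuring exactly when the separation fails.

Power spectra of EEG, MEG and LFP recordings combine a scale-free
aperiodic component, `P(f) ∝ 1/f^β`, with periodic peaks produced by
neural oscillations. The exponent β is widely used as a physiological
readout (e.g. of excitation–inhibition balance), but estimating it
requires removing the peaks — and every removal method has failure
modes: high-frequency noise plateaus, oscillations crossing the fitting
range borders, hidden low-frequency oscillations, broad or overlapping
peaks, and resampling ranges that silently extend beyond the data.

This package is for researchers who estimate 1/f exponents and want to
know when to trust them. It provides:

* **`aperiodic.sim`** — a simulator whose series have *exactly* known
  spectral ground truth: a constructed `C·f^(−β)` Fourier power spectrum
  with Gaussian peaks, uniform-random phases, inverse FFT, plus white
  noise, highpass filtering and sawtooth (spike-wave) transients.
* **`aperiodic.specparam`** — an iterative Gaussian-peak parameterizer:
  robust aperiodic line in log–log space, peaks extracted from the
  flattened spectrum above a 2·SD threshold, final aperiodic re-fit
  (offset, β, optional knee).
* **`aperiodic.irasa`** — irregular-resampling auto-spectral analysis:
  geometric means of (h, 1/h)-resampled PSD pairs, median across the
  h-set (default 1.1…1.9, 17 factors), with the evaluated-range safety
  arithmetic `f_eval = (f_lo/h_max, f_hi·h_max)` enforced by default.
* **`aperiodic.diagnostics`** — plateau-onset detection by sliding
  50 Hz-window fits, logarithmic peak widths `log10(f2/f1)`, the naive
  straight-line exponent, and fitting-range border sweeps.
* **`aperiodic.challenges`** — a registry of eight scenario experiments
  that reproduce the documented failure modes against simulated ground
  truth, with a command-line interface.

## Worked example: one noisy spectrum, three estimators

Simulate 180 s of β = 2 activity at 2400 Hz with enough white noise to
produce a spectral plateau around 100 Hz, then estimate the exponent
three ways:

```sh
cat > demo.cfg <<EOF
beta = 2.0
duration_s = 180
f_sample = 2400
white_noise_scale = 0.65
seed = 7
EOF
aperiodic simulate --spec demo.cfg --out demo_series.txt
aperiodic fit irasa     --ts demo_series.txt --range 2 80
aperiodic fit specparam --ts demo_series.txt --range 1 100
aperiodic fit straight  --ts demo_series.txt --range 1 95
```

Output (abridged):

```
exponent = 1.2225            # irasa, fitting 2-80 Hz
evaluated_range_hz = 1.053 152
exponent = 1.0839            # specparam, fitting 1-100 Hz
exponent = 1.4253            # straight line, 1-95 Hz
```

The truth is β = 2.0, and every estimator misses it badly — which is the
point. The noise plateau flattens the spectrum well below the nominal
fitting ranges: the parameterizer fits straight through the bend, the
straight-line estimator averages over it, and the resampling separator,
although nominally fitting only 2–80 Hz, actually evaluates 1–152 Hz
(printed above) because up-sampling by 1.9 drags the plateau into view.
Diagnosing this — detecting the plateau onset, computing the evaluated
range *before* fitting, choosing borders that avoid both — is what the
`diagnose` command and the diagnostics module are for. On a clean
spectrum (`white_noise_scale = 0`), the same three commands agree with
the truth to two decimals.

Run the full failure-mode experiments with:

```sh
aperiodic challenge list
aperiodic challenge run plateau_bias --seeds 10 --out reports/
```

## Layout

```
src/aperiodic/   sim, psd, specparam, irasa, diagnostics, challenges, cli
tests/           pytest suite (unit, property and end-to-end scenario tests)
docs/methods.md  model, algorithms, parameter choices, limitations
scripts/         acceptance.py
```
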