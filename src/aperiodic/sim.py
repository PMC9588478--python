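"""Simulate time series with exactly known spectral ground truth.

The simulator works in the frequency domain: a one-sided Fourier *power*
spectrum is constructed as a power law ``C * f**-beta`` optionally
multiplied by Gaussian peak terms, uniform-random phases are attached,
and the inverse FFT yields the time series.  Because the spectrum is
built rather than estimated, the aperiodic exponent, peak positions and
peak shapes of the result are known exactly — the property every other
module of this package is evaluated against.

Conventions
-----------
* A peak with relative amplitude ``A`` multiplies the aperiodic power as
  ``1 + A * exp(-(f - f_center)**2 / (2 * sigma_f**2))``, so ``A`` is the
  peak height relative to the aperiodic power at the center frequency
  (``log10(1 + A)`` decades in log power).  Published toolboxes differ
  here (some add peaks in log power); the multiplicative convention keeps
  ``A`` dimensionless and interpretable.
* The DC bin is set to zero power (the power law diverges at f = 0 and
  DC is excluded from every fit anyway), which also makes the series
  exactly zero-mean.
* The normalization ``C`` is chosen so the noiseless series has unit
  variance; ``white_noise_scale`` is therefore an SNR-like quantity.
* One seeded generator draws first the Fourier phases, then the white
  noise, so a spec with noise disabled shares its fractal realization
  with the same spec with noise enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class SpectralPeakSpec:
    """A Gaussian peak in the constructed Fourier power spectrum.

    Parameters
    ----------
    f_center : float
        Center frequency in Hz, > 0.
    amplitude : float
        Peak power gain relative to the aperiodic power at ``f_center``
        (dimensionless, >= 0); the constructed power is multiplied by
        ``1 + amplitude * gaussian(f)``.
    sigma_f : float
        Spectral standard deviation in Hz, > 0.
    """

    f_center: float
    amplitude: float
    sigma_f: float

    def __post_init__(self) -> None:
        if not self.f_center > 0:
            raise ValueError(f"f_center must be > 0, got {self.f_center}")
        if not self.sigma_f > 0:
            raise ValueError(f"sigma_f must be > 0, got {self.sigma_f}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def gain(self, freqs: np.ndarray) -> np.ndarray:
        """Multiplicative power gain ``1 + A * gaussian`` on ``freqs``."""
        g = np.exp(-((freqs - self.f_center) ** 2) / (2.0 * self.sigma_f**2))
        return 1.0 + self.amplitude * g


@dataclass(frozen=True)
class TransientSpec:
    """A transient non-sinusoidal oscillation added in the time domain.

    Only sawtooth transients are supported: they emulate the spike-wave
    discharges of absence seizures, whose harmonics contaminate broad
    parts of the spectrum.  The sawtooth is zero-mean, starts at a rising
    zero crossing at ``interval[0]``, and ``amplitude`` is half the
    peak-to-peak excursion (time-domain units).

    ``width`` is the fraction of each period spent rising.  The ideal
    ramp (``width = 1``, the default) has harmonic amplitudes falling as
    1/k, i.e. harmonic power proportional to 1/k^2.  Real spike-wave
    discharges have finite slew, making the harmonics fall off roughly
    one order faster; ``width`` slightly below 1 emulates that.
    """

    kind: str = "sawtooth"
    frequency: float = 3.0
    amplitude: float = 1.0
    interval: tuple[float, float] = (0.0, 1.0)
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind != "sawtooth":
            raise ValueError(f"unsupported transient kind {self.kind!r}")
        if not self.frequency > 0:
            raise ValueError("transient frequency must be > 0")
        start, end = self.interval
        if not start < end:
            raise ValueError(f"interval must satisfy start < end, got {self.interval}")
        if start < 0:
            raise ValueError("interval start must be >= 0")
        if not 0 < self.width <= 1:
            raise ValueError("width must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth recipe for one synthetic series.

    ``beta`` is the 1/f exponent of the constructed power law, ``peaks``
    the periodic structure, ``white_noise_scale`` the standard deviation
    of additive Gaussian noise (in units of the unit-variance noiseless
    series; 0 disables it), ``highpass_hz`` an optional zero-phase
    4th-order Butterworth highpass emulating hardware filtering, and
    ``seed`` drives phases and noise.

    ``f_construct_min`` bounds the constructed power law from below:
    bins under this frequency get zero power.  An unbounded ``f**-beta``
    would place most of the series variance at arbitrarily slow
    fluctuations that no recording amplifier passes (the emulated
    acquisition systems highpass at 0.3-1 Hz) and whose spectral leakage
    measurably steepens the estimated spectrum near the lower fit
    border.  The default of 0.3 Hz is the lowest hardware cutoff among
    the emulated recording systems.
    """

    beta: float
    duration_s: float = 180.0
    f_sample: float = 2400.0
    peaks: tuple[SpectralPeakSpec, ...] = ()
    white_noise_scale: float = 0.0
    transients: tuple[TransientSpec, ...] = ()
    highpass_hz: float | None = None
    f_construct_min: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta}")
        n = self.duration_s * self.f_sample
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise ValueError(
                f"duration_s * f_sample must be a positive integer sample "
                f"count, got {n}"
            )
        for p in self.peaks:
            if p.f_center >= self.f_sample / 2:
                raise ValueError(
                    f"peak at {p.f_center} Hz is at or above the Nyquist "
                    f"frequency {self.f_sample / 2} Hz"
                )
        if self.white_noise_scale < 0:
            raise ValueError("white_noise_scale must be >= 0")
        if self.highpass_hz is not None and not 0 < self.highpass_hz < self.f_sample / 2:
            raise ValueError("highpass_hz must lie in (0, Nyquist)")
        if self.f_construct_min < 0:
            raise ValueError("f_construct_min must be >= 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "transients", tuple(self.transients))
        for t in self.transients:
            if t.interval[1] > self.duration_s + 1e-9:
                raise ValueError(
                    f"transient interval {t.interval} exceeds duration "
                    f"{self.duration_s} s"
                )

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.f_sample)


@dataclass
class TimeSeries:
    """A single-channel real-valued series with sampling rate and provenance."""

    samples: np.ndarray
    f_sample: float
    spec: SimulationSpec | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.f_sample

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.f_sample

    def segment(self, start_s: float, end_s: float) -> "TimeSeries":
        """Slice ``[start_s, end_s)``; provenance is carried along."""
        i0 = int(round(start_s * self.f_sample))
        i1 = int(round(end_s * self.f_sample))
        if not 0 <= i0 < i1 <= self.n:
            raise ValueError(f"segment ({start_s}, {end_s}) s out of bounds")
        return TimeSeries(self.samples[i0:i1], self.f_sample, spec=self.spec)

    def save(self, path) -> None:
        """Write as two-column delimited text ``time_s value``."""
        header = f"f_sample_hz = {self.f_sample}"
        np.savetxt(path, np.column_stack([self.times, self.samples]),
                   header=header, fmt="%.10g")

    @classmethod
    def load(cls, path, f_sample: float | None = None) -> "TimeSeries":
        data = np.loadtxt(path)
        if data.ndim == 1:  # single column: values only, f_sample required
            if f_sample is None:
                raise ValueError("single-column input requires f_sample")
            return cls(data, f_sample)
        t, x = data[:, 0], data[:, 1]
        if f_sample is None:
            dt = np.diff(t)
            f_sample = 1.0 / float(np.median(dt))
            # snap rates that are integer up to text round-off
            if abs(f_sample - round(f_sample)) < 1e-4 * f_sample:
                f_sample = float(round(f_sample))
        return cls(x, f_sample)


def _construction_grid(spec: SimulationSpec) -> tuple[np.ndarray, float]:
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.f_sample)
    df = spec.f_sample / n
    return freqs, df


def constructed_spectrum(
    spec: SimulationSpec, include_peaks: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectral density the simulator builds for ``spec``.

    Returns the rfft frequency grid of the full series and the target
    density (units^2/Hz).  With ``include_peaks=False`` the pure
    power-law component is returned (same normalization ``C``, which is
    always computed from the full peaky spectrum so that the two share
    the aperiodic baseline).  White noise, highpass filtering and
    transients are *not* part of the constructed spectrum; they are
    applied afterwards in the time domain.
    """
    freqs, df = _construction_grid(spec)
    power = np.zeros_like(freqs)
    power[1:] = freqs[1:] ** (-spec.beta)
    power[freqs < spec.f_construct_min] = 0.0
    full = power.copy()
    for p in spec.peaks:
        full[1:] *= p.gain(freqs[1:])
    c = 1.0 / (np.sum(full[1:]) * df)  # unit variance of the noiseless series
    if include_peaks:
        return freqs, c * full
    return freqs, c * power


def aperiodic_truth_density(
    spec: SimulationSpec, freqs: np.ndarray
) -> np.ndarray:
    """Ground-truth aperiodic density ``C * f**-beta`` plus the white-noise floor.

    White noise of standard deviation ``s`` sampled at ``f_sample``
    contributes a flat one-sided density ``2 * s**2 / f_sample``.
    Highpass filtering is ignored (the truth refers to the unfiltered
    power law).
    """
    grid, dens = constructed_spectrum(spec, include_peaks=False)
    out = np.interp(freqs, grid[1:], dens[1:])
    out = out + 2.0 * spec.white_noise_scale**2 / spec.f_sample
    return out


def synthesize(spec: SimulationSpec) -> TimeSeries:
    """Generate the time series for ``spec``.

    The one-sided Fourier power spectrum of the returned series equals
    the constructed spectrum bin-for-bin (before noise, filtering and
    transients) — an exact inverse-transform round trip, not an
    approximation.  Phases are uniform random; the Nyquist bin (present
    for even sample counts) gets a random sign so that it stays real
    while carrying its full target power.
    """
    n = spec.n_samples
    fs = spec.f_sample
    freqs, density = constructed_spectrum(spec)
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)

    # |X_k|^2 chosen so the boxcar periodogram density equals `density`.
    amp = np.sqrt(density * fs * n / 2.0)
    coeffs = amp * np.exp(1j * phases)
    coeffs[0] = 0.0
    if n % 2 == 0:  # real Nyquist bin, full (unhalved) power, random sign
        coeffs[-1] = np.sqrt(density[-1] * fs * n) * np.sign(np.cos(phases[-1]))
    x = np.fft.irfft(coeffs, n=n)

    if spec.highpass_hz is not None:
        sos = signal.butter(4, spec.highpass_hz, btype="highpass", fs=fs,
                            output="sos")
        x = signal.sosfiltfilt(sos, x)
    if spec.white_noise_scale > 0:
        x = x + rng.normal(0.0, spec.white_noise_scale, n)

    ts = TimeSeries(x, fs, spec=spec)
    for t in spec.transients:
        ts = inject_transient(ts, t)
    return ts


def inject_transient(ts: TimeSeries, transient: TransientSpec) -> TimeSeries:
    """Add a zero-mean sawtooth to ``ts`` inside ``transient.interval``.

    Samples outside the interval are unchanged.  The sawtooth rises
    through zero at the interval start and its harmonics carry power
    proportional to ``1/k**2`` at ``k * frequency``.
    """
    start_s, end_s = transient.interval
    i0 = int(round(start_s * ts.f_sample))
    i1 = int(round(end_s * ts.f_sample))
    if not 0 <= i0 < i1 <= ts.n:
        raise ValueError(
            f"transient interval {transient.interval} s is outside the "
            f"{ts.duration_s} s series"
        )
    out = ts.samples.copy()
    if transient.amplitude != 0.0:
        t_rel = (np.arange(i0, i1) / ts.f_sample) - start_s
        # phase pi: the scipy sawtooth rises from -1, so shift to start at 0
        wave = signal.sawtooth(
            2.0 * np.pi * transient.frequency * t_rel + np.pi,
            width=transient.width,
        )
        out[i0:i1] += transient.amplitude * wave
    return TimeSeries(out, ts.f_sample, spec=ts.spec)


def calibrate_noise_for_plateau(
    spec: SimulationSpec,
    target_onset_hz: float,
    *,
    n_avg: int = 10,
    start_hz: float = 1.0,
    window_hz: float = 50.0,
    step_hz: float = 1.0,
    beta_thresh: float = 0.05,
    segment_s: float = 1.0,
    max_iter: int = 40,
    initial_scale: float = 0.05,
) -> float:
    """Noise scale placing the detected spectral plateau onset at a target.

    The high-frequency plateau of real recordings comes from white
    measurement noise whose amplitude is never known in advance; this
    routine inverts the plateau detector by monotone bisection on
    ``white_noise_scale``.  Because the detector is a first-passage scan
    (it fires at the first window whose fitted exponent dips below
    threshold), its output on a single estimated PSD scatters by tens of
    Hz; the calibration therefore targets the *mean* detected onset over
    ``n_avg`` independent realizations (seeds ``spec.seed ..
    spec.seed + n_avg - 1``), each detected on its own single-realization
    PSD exactly as the detector is used in practice.

    Returns the calibrated scale; raises ``ValueError`` if the target
    cannot be bracketed (e.g. the target lies below the scan start, or
    no noise level up to the expansion cap produces an onset that low).
    """
    from aperiodic.diagnostics import detect_plateau_onset
    from aperiodic.psd import welch_psd

    nyquist = spec.f_sample / 2.0
    if not start_hz + window_hz < target_onset_hz < nyquist - window_hz:
        raise ValueError(
            f"target onset {target_onset_hz} Hz is not bracketable: must lie "
            f"in ({start_hz + window_hz}, {nyquist - window_hz}) Hz"
        )

    def onset_at(scale: float) -> float:
        onsets = []
        for k in range(n_avg):
            s = replace(spec, white_noise_scale=scale, seed=spec.seed + k)
            p = welch_psd(synthesize(s), segment_s=segment_s)
            rep = detect_plateau_onset(
                p, start_hz=start_hz, window_hz=window_hz,
                step_hz=step_hz, beta_thresh=beta_thresh,
            )
            if rep.onset_hz is None:
                return math.inf
            onsets.append(rep.onset_hz)
        return float(np.mean(onsets))

    lo = 0.0  # pure power law: never plateaus below Nyquist
    hi = initial_scale
    for _ in range(20):
        onset = onset_at(hi)
        if onset <= target_onset_hz:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise ValueError(
            f"could not bracket target onset {target_onset_hz} Hz: noise "
            f"scale {hi} still gives onset {onset} Hz"
        )
    if onset_at(max(lo, 1e-12)) <= target_onset_hz and lo > 0:
        raise ValueError(
            f"noise scale {lo} already places the onset at or below the "
            f"target {target_onset_hz} Hz; target not bracketable from below"
        )

    best_scale, best_gap = hi, abs(onset - target_onset_hz)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        onset = onset_at(mid)
        gap = abs(onset - target_onset_hz) if math.isfinite(onset) else math.inf
        if gap < best_gap:
            best_scale, best_gap = mid, gap
        if onset > target_onset_hz:
            lo = mid
        else:
            hi = mid
        if best_gap <= step_hz or (hi - lo) / hi < 1e-3:
            break
    return best_scale


# ---------------------------------------------------------------------------
# Flat key-value serialization of simulation recipes
# ---------------------------------------------------------------------------

def spec_to_config(spec: SimulationSpec) -> str:
    """Serialize a :class:`SimulationSpec` as flat ``key = value`` text.

    Peaks are encoded one per line as ``peak = f_center,amplitude,sigma_f``
    and transients as ``transient = kind,frequency,amplitude,start,end``
    (SI units throughout).
    """
    lines = [
        f"beta = {spec.beta}",
        f"duration_s = {spec.duration_s}",
        f"f_sample = {spec.f_sample}",
        f"white_noise_scale = {spec.white_noise_scale}",
        f"f_construct_min = {spec.f_construct_min}",
        f"seed = {spec.seed}",
    ]
    if spec.highpass_hz is not None:
        lines.append(f"highpass_hz = {spec.highpass_hz}")
    for p in spec.peaks:
        lines.append(f"peak = {p.f_center},{p.amplitude},{p.sigma_f}")
    for t in spec.transients:
        lines.append(
            f"transient = {t.kind},{t.frequency},{t.amplitude},"
            f"{t.interval[0]},{t.interval[1]},{t.width}"
        )
    return "\n".join(lines) + "\n"


def spec_from_config(text: str) -> SimulationSpec:
    """Parse the flat key-value format written by :func:`spec_to_config`."""
    scalars: dict[str, float] = {}
    peaks: list[SpectralPeakSpec] = []
    transients: list[TransientSpec] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "peak":
            fc, a, sf = (float(v) for v in value.split(","))
            peaks.append(SpectralPeakSpec(fc, a, sf))
        elif key == "transient":
            parts = value.split(",")
            transients.append(TransientSpec(
                kind=parts[0].strip(), frequency=float(parts[1]),
                amplitude=float(parts[2]),
                interval=(float(parts[3]), float(parts[4])),
                width=float(parts[5]) if len(parts) > 5 else 1.0,
            ))
        else:
            scalars[key] = float(value)
    known = {"beta", "duration_s", "f_sample", "white_noise_scale", "seed",
             "highpass_hz", "f_construct_min"}
    unknown = set(scalars) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "beta" not in scalars:
        raise ValueError("config missing required key 'beta'")
    return SimulationSpec(
        beta=scalars["beta"],
        duration_s=scalars.get("duration_s", 180.0),
        f_sample=scalars.get("f_sample", 2400.0),
        peaks=tuple(peaks),
        white_noise_scale=scalars.get("white_noise_scale", 0.0),
        transients=tuple(transients),
        highpass_hz=scalars.get("highpass_hz"),
        f_construct_min=scalars.get("f_construct_min", 0.3),
        seed=int(scalars.get("seed", 0)),
    )
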