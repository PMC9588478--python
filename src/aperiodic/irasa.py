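"""Irregular-resampling auto-spectral analysis (IRASA).

A fractal (scale-free) time series has a power spectrum that is
invariant under resampling: stretching time by a factor ``h`` maps
``f**-beta`` onto ``h**-beta * f**-beta``, and the geometric mean of the
up- and downsampled spectra restores ``f**-beta`` exactly.  Periodic
peaks, in contrast, are displaced to ``cf * h`` and ``cf / h``.  Taking
the per-bin median of the geometric means over a set of resampling
factors therefore removes the peaks and leaves the aperiodic component;
the periodic component is the remainder of the original PSD.

The central safety arithmetic: with maximum resampling factor
``h_max``, a nominal fitting range ``(f_lo, f_hi)`` actually draws on
original-spectrum content over the *evaluated* range
``(f_lo / h_max, f_hi * h_max)``, and the strongest downsampling lowers
the usable Nyquist frequency to ``f_sample / (2 * h_max)``.  Violations
of these bounds (evaluated range crossing a known highpass stopband or
the resampled Nyquist) raise :class:`EvaluatedRangeError` by default;
passing ``strict=False`` runs the separation anyway, which is exactly
how the documented failure modes are demonstrated.

Implementation notes: non-integer factors use rational-approximation
polyphase resampling (anti-aliasing lowpass at the lower Nyquist of
each pair, factor approximated to a relative tolerance of 1e-4); up- and
downsampled PSDs use the same segment duration in seconds and are
interpolated onto the original Welch grid in log power, which preserves
power-law straightness.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from aperiodic.psd import PSD, welch_psd
from aperiodic.sim import TimeSeries
from aperiodic.specparam import AperiodicFit, _ols_line

_H_TOL = 1e-4


class EvaluatedRangeError(ValueError):
    """The evaluated frequency range violates a spectral bound."""


@dataclass(frozen=True)
class HSet:
    """Ascending set of resampling factors, all > 1."""

    factors: tuple[float, ...]

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.factors)
        if not f:
            raise ValueError("h_set must not be empty")
        if any(x <= 1.0 for x in f):
            raise ValueError("all resampling factors must be > 1")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("resampling factors must be strictly ascending")
        object.__setattr__(self, "factors", f)

    @property
    def h_max(self) -> float:
        return self.factors[-1]

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)

    @classmethod
    def default(cls) -> "HSet":
        """The standard set: 1.1 to 1.9 in steps of 0.05 (17 factors)."""
        return cls(tuple(np.round(np.arange(22, 39) * 0.05, 10)))

    @classmethod
    def up_to(cls, h_max: float, n: int = 9, h_min: float = 1.1) -> "HSet":
        """``n`` factors evenly spaced from ``h_min`` to ``h_max``."""
        if not h_max > h_min:
            raise ValueError("h_max must exceed h_min")
        return cls(tuple(np.linspace(h_min, h_max, n)))


@dataclass(frozen=True)
class EvaluatedRange:
    """The band actually examined after resampling (wider than the fit range)."""

    f_eval_min: float
    f_eval_max: float


def evaluated_range(fit_range: tuple[float, float], h_max: float) -> EvaluatedRange:
    """``(f_lo / h_max, f_hi * h_max)`` — exact arithmetic, no rounding."""
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    f_lo, f_hi = fit_range
    return EvaluatedRange(f_lo / h_max, f_hi * h_max)


def resampled_nyquist(f_sample: float, h_max: float) -> float:
    """Highest frequency surviving the strongest downsampling."""
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    return f_sample / (2.0 * h_max)


def _as_fraction(h: float) -> Fraction:
    for limit in (1000, 10000, 100000):
        frac = Fraction(h).limit_denominator(limit)
        if abs(float(frac) - h) <= _H_TOL * h:
            return frac
    raise ValueError(f"cannot approximate resampling factor {h} rationally")


def _pair_geometric_mean(
    x: np.ndarray, fs: float, h: float, segment_s: float, ref_freqs: np.ndarray
) -> np.ndarray:
    """Geometric mean of the (h, 1/h) PSD pair on ``ref_freqs`` (log-interp).

    Both resampled series keep the *original* declared sampling rate, so
    upsampling by ``h`` compresses spectral features to ``f / h`` and
    downsampling displaces them to ``f * h``, while a fractal spectrum
    maps onto ``h**-beta * f**-beta`` and ``h**beta * f**-beta`` whose
    geometric mean restores ``f**-beta`` exactly.
    """
    frac = _as_fraction(h)
    up, down = frac.numerator, frac.denominator
    log_parts = []
    for num, den in ((up, down), (down, up)):
        y = signal.resample_poly(x, num, den)
        p = welch_psd(TimeSeries(y, fs), segment_s=segment_s)
        pos = p.power > 0
        log_parts.append(np.interp(
            ref_freqs, p.freqs[pos], np.log10(p.power[pos])
        ))
    return 10.0 ** (0.5 * (log_parts[0] + log_parts[1]))


def resample_pair_psd(ts: TimeSeries, h: float, segment_s: float = 4.0) -> PSD:
    """PSD geometric mean of one resampling pair ``(h, 1/h)``.

    Returned on the original Welch grid, capped at the downsampled
    Nyquist ``f_sample / (2h)``.  ``h = 1`` returns the plain Welch PSD.
    """
    base = welch_psd(ts, segment_s=segment_s)
    if h == 1.0:
        return base
    if h < 1.0:
        raise ValueError("resampling factor must be >= 1")
    cap = ts.f_sample / (2.0 * h)
    mask = (base.freqs > 0) & (base.freqs <= cap + base.df / 2)
    ref = base.freqs[mask]
    gm = _pair_geometric_mean(ts.samples, ts.f_sample, h, segment_s, ref)
    meta = dict(base.meta)
    meta["h"] = h
    return PSD(ref, gm, meta=meta)


@dataclass
class IrasaResult:
    """Separated spectra plus the exponent fit and range bookkeeping."""

    aperiodic_psd: PSD
    periodic_psd: PSD
    fit: AperiodicFit
    evaluated: EvaluatedRange
    h_set: HSet

    def save(self, path) -> None:
        header = "\n".join([
            f"offset = {self.fit.offset}",
            f"exponent = {self.fit.exponent}",
            f"fit_range = {self.fit.fit_range[0]} {self.fit.fit_range[1]}",
            f"f_eval_min = {self.evaluated.f_eval_min}",
            f"f_eval_max = {self.evaluated.f_eval_max}",
            "h_set = " + " ".join(f"{h:g}" for h in self.h_set),
            "columns: freq_hz aperiodic periodic",
        ])
        np.savetxt(path, np.column_stack([
            self.aperiodic_psd.freqs, self.aperiodic_psd.power,
            self.periodic_psd.power,
        ]), header=header, fmt="%.10g")


def irasa_separate(
    ts: TimeSeries,
    fit_range: tuple[float, float],
    h_set: HSet | None = None,
    segment_s: float = 4.0,
    strict: bool = True,
) -> IrasaResult:
    """Separate ``ts`` into aperiodic and periodic spectral components.

    The aperiodic PSD is the per-bin median over the per-factor
    geometric means; the periodic PSD is the original Welch PSD minus
    the aperiodic one (so the two reconstruct the input exactly).  The
    1/f exponent is an ordinary least-squares fit of log10 aperiodic
    power on log10 frequency over ``fit_range``.

    With ``strict=True`` (default) the evaluated range is checked
    against the resampled Nyquist frequency and, when the series carries
    simulation provenance, against the highpass cutoff; violations raise
    :class:`EvaluatedRangeError` naming the bound.  The upper fit border
    exceeding the resampled Nyquist is always an error: no data exist
    there in the most-downsampled spectrum.
    """
    if h_set is None:
        h_set = HSet.default()
    f_lo, f_hi = fit_range
    if not 0 < f_lo < f_hi:
        raise ValueError(f"fit_range must satisfy 0 < lo < hi, got {fit_range}")
    if f_hi > ts.f_sample / 2:
        raise ValueError(
            f"upper fitting border {f_hi} Hz exceeds the Nyquist frequency "
            f"{ts.f_sample / 2:g} Hz"
        )
    nyq_res = resampled_nyquist(ts.f_sample, h_set.h_max)
    ev = evaluated_range(fit_range, h_set.h_max)
    if strict:
        if f_hi > nyq_res:
            raise EvaluatedRangeError(
                f"upper fitting border {f_hi} Hz exceeds the resampled "
                f"Nyquist frequency {nyq_res:g} Hz at h_max={h_set.h_max:g}: "
                f"the most-downsampled spectrum carries no signal there"
            )
        if ev.f_eval_max > nyq_res:
            raise EvaluatedRangeError(
                f"evaluated range upper bound {ev.f_eval_max:g} Hz exceeds "
                f"the resampled Nyquist frequency {nyq_res:g} Hz "
                f"(h_max={h_set.h_max:g}); lower h_max or the upper fit border"
            )
        hp = ts.spec.highpass_hz if ts.spec is not None else None
        if hp is not None and ev.f_eval_min < hp:
            raise EvaluatedRangeError(
                f"evaluated range lower bound {ev.f_eval_min:g} Hz falls "
                f"inside the highpass stopband (cutoff {hp:g} Hz); "
                f"raise the lower fit border or lower h_max"
            )

    base = welch_psd(ts, segment_s=segment_s)
    # the grid extends to the resampled Nyquist; beyond it the strongest
    # downsampling carries only anti-aliasing stopband residue, which is
    # exactly the artifact strict mode refuses to fit
    cap = max(nyq_res, f_hi)
    mask = (base.freqs > 0) & (base.freqs <= cap + base.df / 2)
    ref = base.freqs[mask]
    gms = np.empty((len(h_set), ref.size))
    for i, h in enumerate(h_set):
        gms[i] = _pair_geometric_mean(ts.samples, ts.f_sample, h, segment_s, ref)
    aperiodic = np.median(gms, axis=0)
    periodic = base.power[mask] - aperiodic

    fit_mask = (ref >= f_lo - base.df / 2) & (ref <= f_hi + base.df / 2)
    if fit_mask.sum() < 3:
        raise ValueError("fit_range covers fewer than 3 bins")
    off, expo = _ols_line(np.log10(ref[fit_mask]), np.log10(aperiodic[fit_mask]))
    pred = off - expo * np.log10(ref[fit_mask])
    rmse = float(np.sqrt(np.mean((np.log10(aperiodic[fit_mask]) - pred) ** 2)))
    fit = AperiodicFit(off, expo, None, (f_lo, f_hi), rmse)

    meta = dict(base.meta)
    meta["h_max"] = h_set.h_max
    return IrasaResult(
        aperiodic_psd=PSD(ref, aperiodic, meta=dict(meta, component="aperiodic")),
        periodic_psd=PSD(ref, periodic, meta=dict(meta, component="periodic")),
        fit=fit,
        evaluated=ev,
        h_set=h_set,
    )
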