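"""Spectrum-quality statistics for 1/f estimation.

These diagnostics answer the questions that decide whether an aperiodic
fit is trustworthy: where does the white-noise plateau begin (upper
border constraint), how wide are the peaks on a logarithmic frequency
axis (resampling-factor constraint), and how does the estimated
exponent move as the fitting range is swept across the peaks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aperiodic.psd import PSD, welch_psd
from aperiodic.sim import TimeSeries
from aperiodic.specparam import FitParams, fit_spectral_model, _ols_line


@dataclass
class PlateauReport:
    """Result of the sliding-window plateau scan.

    ``onset_hz`` is the lowest window start whose aperiodic-only fitted
    exponent falls below ``beta_thresh`` (None if no window qualifies).
    The scan stops at the first sub-threshold window unless the full
    trace was requested, so ``window_slopes`` covers starts up to and
    including the onset (or the whole band).
    """

    onset_hz: float | None
    window_hz: float
    step_hz: float
    beta_thresh: float
    window_starts: np.ndarray = field(repr=False)
    window_slopes: np.ndarray = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start_hz": self.window_starts,
            "exponent": self.window_slopes,
        })

    def save(self, path) -> None:
        header = (
            f"onset_hz = {'' if self.onset_hz is None else self.onset_hz}\n"
            f"window_hz = {self.window_hz}\n"
            f"step_hz = {self.step_hz}\n"
            f"beta_thresh = {self.beta_thresh}\n"
            "columns: window_start_hz exponent"
        )
        np.savetxt(path, np.column_stack([self.window_starts, self.window_slopes]),
                   header=header, fmt="%.10g")


def _window_exponent(psd: PSD, f_lo: float, f_hi: float) -> float:
    """Aperiodic-only (peak-free) exponent of one window.

    The same estimate the parameterizer reports with peak fitting
    disabled: the final least-squares line in double-log space.
    """
    sel = psd.band(f_lo, f_hi)
    pos = (sel.freqs > 0) & (sel.power > 0)
    _, expo = _ols_line(np.log10(sel.freqs[pos]), np.log10(sel.power[pos]))
    return expo


def detect_plateau_onset(
    psd: PSD,
    start_hz: float = 1.0,
    window_hz: float = 50.0,
    step_hz: float = 1.0,
    beta_thresh: float = 0.05,
    full_trace: bool = False,
) -> PlateauReport:
    """Locate the spectral plateau by sliding a fixed-width fit window.

    Fits the aperiodic exponent (no peak fitting) over ``[f, f +
    window_hz]`` starting at ``start_hz``, shifting by ``step_hz``, and
    reports the first start frequency whose exponent drops below
    ``beta_thresh``.  ``full_trace=True`` keeps scanning past the onset
    so the whole slope-vs-frequency curve is available.
    """
    f_max = psd.freqs[-1]
    if start_hz + window_hz > f_max + psd.df / 2:
        raise ValueError(
            f"PSD band ends at {f_max} Hz: narrower than one {window_hz} Hz "
            f"window from {start_hz} Hz"
        )
    starts, slopes = [], []
    onset = None
    f = start_hz
    while f + window_hz <= f_max + psd.df / 2:
        expo = _window_exponent(psd, f, f + window_hz)
        starts.append(f)
        slopes.append(expo)
        if onset is None and expo < beta_thresh:
            onset = f
            if not full_trace:
                break
        f += step_hz
    return PlateauReport(
        onset_hz=onset, window_hz=window_hz, step_hz=step_hz,
        beta_thresh=beta_thresh,
        window_starts=np.asarray(starts), window_slopes=np.asarray(slopes),
    )


def log_peak_width(f1: float, f2: float) -> float:
    """Logarithmic peak width ``log10(f2 / f1)`` (scale-invariant)."""
    if not 0 < f1 <= f2:
        raise ValueError(f"need 0 < f1 <= f2, got ({f1}, {f2})")
    return math.log10(f2 / f1)


def peak_bounds(
    psd: PSD, aperiodic_truth: PSD, threshold: float = 0.001
) -> list[tuple[float, float]]:
    """Peak frequency bounds from deviation against a known aperiodic truth.

    A bin belongs to a peak when its *relative* deviation
    ``(P - P_truth) / P_truth`` exceeds ``threshold`` (the relative
    convention is the only scale-free one).  Each contiguous run of
    deviating bins yields one ``(f1, f2)`` pair.
    """
    if psd.freqs.shape != aperiodic_truth.freqs.shape or not np.allclose(
        psd.freqs, aperiodic_truth.freqs
    ):
        raise ValueError("PSD and aperiodic truth must share one frequency grid")
    truth = aperiodic_truth.power
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(truth > 0, (psd.power - truth) / truth, 0.0)
    above = rel > threshold
    bounds: list[tuple[float, float]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            bounds.append((float(psd.freqs[i]), float(psd.freqs[j])))
            i = j + 1
        else:
            i += 1
    return bounds


def straight_line_exponent(
    psd: PSD, f_lo: float, f_hi: float, nearest: bool = False
) -> float:
    """Slope magnitude of the line connecting two log-log PSD points.

    The naive reference estimator: no fitting, just the two endpoint
    values.  Endpoints must sit on the grid; with ``nearest=True``
    off-grid endpoints snap to the nearest bin with a warning.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")

    def locate(f: float) -> int:
        i = int(np.argmin(np.abs(psd.freqs - f)))
        if abs(psd.freqs[i] - f) > 1e-6 * max(psd.df, 1e-12):
            if not nearest:
                raise ValueError(
                    f"{f} Hz is not on the frequency grid (spacing {psd.df} Hz); "
                    "pass nearest=True to snap to the closest bin"
                )
            warnings.warn(
                f"endpoint {f} Hz snapped to grid bin {psd.freqs[i]} Hz",
                stacklevel=3,
            )
        return i

    i_lo, i_hi = locate(f_lo), locate(f_hi)
    p_lo, p_hi = psd.power[i_lo], psd.power[i_hi]
    if p_lo <= 0 or p_hi <= 0:
        raise ValueError("endpoint power must be > 0")
    return -(math.log10(p_hi) - math.log10(p_lo)) / (
        math.log10(psd.freqs[i_hi]) - math.log10(psd.freqs[i_lo])
    )


@dataclass
class SweepResult:
    """Exponent estimates across a sweep of lower fitting-range borders."""

    lower_borders: np.ndarray
    estimates: np.ndarray
    abs_error: np.ndarray
    method: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lower_border_hz": self.lower_borders,
            "estimate": self.estimates,
            "abs_error": self.abs_error,
            "method": self.method,
        })


def sweep_lower_border(
    ts: TimeSeries,
    method: str,
    upper_hz: float = 100.0,
    borders=None,
    beta_truth: float | None = None,
    fit_params_factory=None,
    h_set=None,
) -> SweepResult:
    """Estimate the 1/f exponent for every lower fitting-range border.

    ``method`` is one of ``specparam`` (full parameterization per
    border, 1 s Welch segments), ``irasa`` (one separation, then a
    per-border line fit of the aperiodic spectrum) or ``straight``
    (endpoint arithmetic).  Ground truth comes from the simulation
    provenance unless ``beta_truth`` is given.  Per-border failures
    yield NaN entries; the sweep never aborts.
    """
    from aperiodic.irasa import irasa_separate
    from aperiodic.specparam import _ols_line

    if borders is None:
        borders = np.arange(1.0, 81.0)
    borders = np.asarray(borders, dtype=float)
    if beta_truth is None:
        if ts.spec is None:
            raise ValueError("beta_truth required when ts has no provenance")
        beta_truth = ts.spec.beta

    estimates = np.full(borders.size, np.nan)
    if method == "specparam":
        psd = welch_psd(ts, segment_s=1.0)
        for k, b in enumerate(borders):
            try:
                fp = (FitParams(fit_range=(b, upper_hz))
                      if fit_params_factory is None else fit_params_factory(b))
                estimates[k] = fit_spectral_model(psd, fp).aperiodic.exponent
            except (ValueError, RuntimeError):
                pass
    elif method == "irasa":
        res = irasa_separate(ts, (float(borders.min()), upper_hz), h_set=h_set)
        ap = res.aperiodic_psd
        for k, b in enumerate(borders):
            try:
                band = ap.band(b, upper_hz)
                _, expo = _ols_line(np.log10(band.freqs), np.log10(band.power))
                estimates[k] = expo
            except (ValueError, RuntimeError):
                pass
    elif method == "straight":
        psd = welch_psd(ts, segment_s=1.0)
        for k, b in enumerate(borders):
            try:
                estimates[k] = straight_line_exponent(psd, b, upper_hz,
                                                      nearest=True)
            except ValueError:
                pass
    else:
        raise ValueError(
            f"unknown method {method!r}: use 'specparam', 'irasa' or 'straight'"
        )
    return SweepResult(
        lower_borders=borders, estimates=estimates,
        abs_error=np.abs(beta_truth - estimates), method=method,
    )
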