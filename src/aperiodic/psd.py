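"""Welch power spectral density estimation.

Two configurations are used throughout the package: 1 s Hann segments
with 50% overlap (1 Hz resolution, smooth input for the peak
parameterizer) and 4 s segments (0.25 Hz resolution, used inside the
resampling separator).  Segments are mean-detrended; an incomplete last
segment is dropped; the density is one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from aperiodic.sim import TimeSeries


@dataclass
class PSD:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if self.freqs.size >= 2:
            steps = np.diff(self.freqs)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("frequency grid must be uniformly spaced")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power must be finite")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band(self, f_lo: float, f_hi: float) -> "PSD":
        """Restrict to ``f_lo <= f <= f_hi`` (inclusive, tolerance half a bin)."""
        tol = self.df / 2.0
        mask = (self.freqs >= f_lo - tol) & (self.freqs <= f_hi + tol)
        if not np.any(mask):
            raise ValueError(f"band ({f_lo}, {f_hi}) Hz is empty on this grid")
        return PSD(self.freqs[mask], self.power[mask], meta=dict(self.meta))

    def save(self, path) -> None:
        header = "\n".join(f"{k} = {v}" for k, v in self.meta.items())
        header += ("\n" if header else "") + "columns: freq_hz power"
        np.savetxt(path, np.column_stack([self.freqs, self.power]),
                   header=header, fmt="%.10g")

    @classmethod
    def load(cls, path) -> "PSD":
        meta: dict = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if "=" in body:
                    k, v = (s.strip() for s in body.split("=", 1))
                    try:
                        meta[k] = float(v)
                    except ValueError:
                        meta[k] = v
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1], meta=meta)


def welch_psd(
    ts: TimeSeries,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> PSD:
    """Welch PSD of ``ts`` with segment length given in seconds.

    Grid spacing is ``1 / segment_s``; the density integrates to
    approximately the series variance (Parseval, up to windowing bias).
    """
    nperseg = int(round(segment_s * ts.f_sample))
    if nperseg < 2:
        raise ValueError(f"segment of {segment_s} s is shorter than 2 samples")
    if ts.n < nperseg:
        raise ValueError(
            f"series of {ts.duration_s:.3g} s is shorter than one "
            f"{segment_s} s segment"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be a fraction in [0, 1)")
    freqs, power = signal.welch(
        ts.samples,
        fs=ts.f_sample,
        window=window,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        return_onesided=True,
        scaling="density",
    )
    meta = {
        "segment_s": segment_s,
        "window": window,
        "overlap": overlap,
        "f_sample": ts.f_sample,
    }
    return PSD(freqs, power, meta=meta)
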