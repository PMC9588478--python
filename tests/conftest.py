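import numpy as np
import pytest

from aperiodic import PSD, SimulationSpec, SpectralPeakSpec, synthesize


@pytest.fixture(scope="session")
def power_law_psd():
    """Exact noiseless power-law PSD factory on an integer-Hz grid."""

    def make(beta, f_lo=1.0, f_hi=100.0, offset=1.0):
        freqs = np.arange(f_lo, f_hi + 1.0)
        return PSD(freqs, offset * freqs ** (-beta))

    return make


@pytest.fixture(scope="session")
def short_series():
    """A 30 s beta=1.5 series at 1200 Hz, shared across read-only tests."""
    return synthesize(SimulationSpec(beta=1.5, duration_s=30, f_sample=1200,
                                     seed=11))


@pytest.fixture(scope="session")
def peaky_series():
    """A 60 s series with one narrow alpha peak, shared across read-only tests."""
    spec = SimulationSpec(
        beta=1.0, duration_s=60, f_sample=1200,
        peaks=(SpectralPeakSpec(10.0, 6.0, 0.5),), seed=5,
    )
    return synthesize(spec)
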