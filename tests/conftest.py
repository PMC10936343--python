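"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phasorflim import AcquisitionParams, FlimStack


@pytest.fixture
def params56() -> AcquisitionParams:
    """The emulated acquisition regime: 80 MHz, 56 bins over one period."""
    return AcquisitionParams(
        rep_rate_mhz=80.0, n_bins=56, bin_width_ns=1.0 / (0.08 * 56), harmonic=1
    )


def make_params(n_bins: int, harmonic: int = 1, freq_mhz: float = 80.0):
    return AcquisitionParams(
        rep_rate_mhz=freq_mhz,
        n_bins=n_bins,
        bin_width_ns=1.0 / (freq_mhz * 1e-3 * n_bins),
        harmonic=harmonic,
    )


def geometric_series_phasor(tau_ns: float, n_bins: int, harmonic: int = 1,
                            freq_mhz: float = 80.0) -> complex:
    """Closed-form phasor of a bin-integrated single-exponential decay.

    Bin counts of a (periodic) exponential sampled over one full period
    are geometric, c_k ∝ r^k with r = exp(-Δt/τ), so the normalized DFT
    at harmonic n collapses to (1-r)/(1 - r e^{i 2πn/N}). Independent of
    the package's summation path.
    """
    if tau_ns == 0:
        return complex(1.0, 0.0)
    dt = 1.0 / (freq_mhz * 1e-3 * n_bins)
    r = np.exp(-dt / tau_ns)
    return complex((1 - r) / (1 - r * np.exp(1j * 2 * np.pi * harmonic / n_bins)))


def continuous_phasor(tau_ns: float, freq_mhz: float = 80.0,
                      harmonic: int = 1) -> complex:
    """Ideal-sampling phasor 1/(1 - iωτ) of a single exponential."""
    x = 2 * np.pi * harmonic * freq_mhz * 1e-3 * tau_ns
    return complex(1.0, x) / (1.0 + x * x)


def delta_stack(shape=(4, 4), n_bins=56, photons=1000.0) -> FlimStack:
    """Stack where every pixel has all photons in temporal bin 0."""
    counts = np.zeros(shape + (n_bins,))
    counts[..., 0] = photons
    return FlimStack(counts=counts, source_path="<delta>")
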