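"""Base data containers shared across the package.

A time-domain FLIM acquisition is a per-pixel histogram of photon arrival
times over one laser period: a ``rows x cols x n_bins`` grid of counts
(:class:`FlimStack`) plus the acquisition parameters that fix the angular
frequency of the phasor transform (:class:`AcquisitionParams`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionParams", "FlimStack"]

#: Relative tolerance for the period consistency check T = n_bins * bin_width.
PERIOD_RTOL = 1e-3


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition parameters of a time-domain FLIM measurement.

    Parameters
    ----------
    rep_rate_mhz
        Laser repetition rate ``f`` in MHz. The excitation period is
        ``T = 1/f``.
    n_bins
        Number of temporal bins per period (>= 2).
    bin_width_ns
        Width of one temporal bin in ns. For a full-period acquisition
        ``n_bins * bin_width_ns`` should equal ``T``; a relative mismatch
        beyond 0.1% raises a warning but the supplied width is used as-is.
    harmonic
        Harmonic ``n`` of the repetition rate at which the transform is
        evaluated; the angular frequency is ``omega = 2*pi*n*f``.
    """

    rep_rate_mhz: float
    n_bins: int
    bin_width_ns: float
    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.rep_rate_mhz <= 0:
            raise ValueError("rep_rate_mhz must be positive")
        if int(self.n_bins) != self.n_bins or self.n_bins < 2:
            raise ValueError("n_bins must be an integer >= 2")
        if self.bin_width_ns <= 0:
            raise ValueError("bin_width_ns must be positive")
        if int(self.harmonic) != self.harmonic or self.harmonic < 1:
            raise ValueError("harmonic must be a positive integer")
        period = self.period_ns
        covered = self.n_bins * self.bin_width_ns
        if abs(covered - period) > PERIOD_RTOL * period:
            warnings.warn(
                f"n_bins * bin_width_ns = {covered:.6g} ns does not match the "
                f"laser period 1/f = {period:.6g} ns; proceeding with the "
                "supplied bin width",
                stacklevel=3,
            )

    @property
    def period_ns(self) -> float:
        """Excitation period ``T = 1/f`` in ns."""
        return 1.0 / (self.rep_rate_mhz * 1e-3)

    @property
    def omega(self) -> float:
        """Angular frequency ``2*pi*harmonic*f`` in rad/ns."""
        return 2.0 * np.pi * self.harmonic * self.rep_rate_mhz * 1e-3

    @property
    def bin_times_ns(self) -> np.ndarray:
        """Left-edge time coordinate of every bin, ``t_k = k * bin_width_ns``."""
        return np.arange(self.n_bins) * self.bin_width_ns


@dataclass
class FlimStack:
    """A 3-D photon-count histogram: ``counts[row, col, bin]``.

    Row index 0 is the top image row. Counts are stored as float64 so that
    noiseless synthetic expectations (non-integer) can flow through the same
    pipeline as measured integer counts; all values must be non-negative.
    """

    counts: np.ndarray
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.ndim != 3:
            raise ValueError("counts must be a rows x cols x n_bins array")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if counts.shape[2] < 2:
            raise ValueError("fewer than 2 temporal bins")
        if np.any(counts < 0):
            raise ValueError("negative counts are not allowed")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape ``(rows, cols)``."""
        return self.counts.shape[:2]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]
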