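"""Phasor transform, calibration, and lifetime estimation.

The phasor of a pixel's decay histogram ``c_k`` at angular frequency
``omega`` is the normalized first Fourier coefficient

    g = sum_k c_k cos(omega t_k) / sum_k c_k
    s = sum_k c_k sin(omega t_k) / sum_k c_k

with ``t_k = k * bin_width`` (left bin edge) and ``omega = 2*pi*n*f``.
Single-exponential decays fall on the universal semicircle of radius 1/2
centered at (1/2, 0); mixtures fall inside it. Instrument response is
corrected by an affine phase/modulation calibration measured on a standard
of known lifetime, after which phase and modulation each invert to a
lifetime estimate (tau_phi and tau_M).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import AcquisitionParams, FlimStack

__all__ = [
    "PhasorField",
    "CalibrationTransform",
    "LifetimeMaps",
    "phasor_transform",
    "phase_modulation",
    "theoretical_phasor",
    "compute_calibration",
    "apply_calibration",
    "lifetime_maps",
]


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates plus intensity and provenance.

    ``unfiltered_g``/``unfiltered_s`` hold pristine copies of the
    coordinates as produced by the transform (and calibration), so that
    median filtering is reversible. They are write-protected.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    params: AcquisitionParams
    calibrated: bool = False
    median_passes_applied: int = 0
    unfiltered_g: np.ndarray | None = None
    unfiltered_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.g.shape == self.s.shape == self.intensity.shape):
            raise ValueError("g, s and intensity must share dimensions")
        if self.median_passes_applied < 0:
            raise ValueError("median_passes_applied must be >= 0")
        if self.unfiltered_g is None:
            self.unfiltered_g = self.g.copy()
        if self.unfiltered_s is None:
            self.unfiltered_s = self.s.copy()
        self.unfiltered_g.setflags(write=False)
        self.unfiltered_s.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape


@dataclass(frozen=True)
class CalibrationTransform:
    """Instrument phase offset and modulation correction factor.

    Applying the transform subtracts ``phase_offset_rad`` from every
    pixel's phase and multiplies its modulation by ``modulation_factor``,
    mapping the measured reference phasor onto the theoretical phasor of
    ``reference_lifetime_ns``.
    """

    phase_offset_rad: float
    modulation_factor: float
    harmonic: int
    reference_lifetime_ns: float

    def __post_init__(self) -> None:
        if self.modulation_factor <= 0:
            raise ValueError("modulation_factor must be positive")
        if self.reference_lifetime_ns < 0:
            raise ValueError("reference_lifetime_ns must be >= 0")

    @classmethod
    def identity(cls, harmonic: int = 1) -> "CalibrationTransform":
        return cls(0.0, 1.0, harmonic, 0.0)


@dataclass(frozen=True)
class LifetimeMaps:
    """Phase lifetime tau_phi = tan(phi)/omega and modulation lifetime
    tau_M = sqrt(1/m^2 - 1)/omega, in ns. NaN marks pixels where the
    estimator is undefined (phase outside [0, pi/2), modulation > 1 or 0)."""

    taup_ns: np.ndarray
    taum_ns: np.ndarray


def phasor_transform(stack: FlimStack, params: AcquisitionParams) -> PhasorField:
    """Transform a decay stack to per-pixel phasor coordinates.

    Pixels with zero total counts get NaN coordinates; an entirely empty
    stack additionally raises a warning.
    """
    if stack.n_bins != params.n_bins:
        raise ValueError(
            f"stack has {stack.n_bins} bins but params declare {params.n_bins}"
        )
    phases = params.omega * params.bin_times_ns
    cos_t = np.cos(phases)
    sin_t = np.sin(phases)
    counts = stack.counts
    intensity = counts.sum(axis=2)
    if not np.any(intensity > 0):
        warnings.warn("stack has no photons; every pixel is undefined", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (counts @ cos_t) / intensity
        s = (counts @ sin_t) / intensity
    empty = intensity == 0
    g[empty] = np.nan
    s[empty] = np.nan
    return PhasorField(g=g, s=s, intensity=intensity, params=params)


def phase_modulation(field: PhasorField) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel phase ``phi = atan2(s, g)`` and modulation ``m = |(g, s)|``."""
    phi = np.arctan2(field.s, field.g)
    m = np.hypot(field.g, field.s)
    undefined = ~(np.isfinite(field.g) & np.isfinite(field.s))
    phi[undefined] = np.nan
    m[undefined] = np.nan
    return phi, m


def theoretical_phasor(tau_ns, params: AcquisitionParams):
    """Phasor of an ideal single-exponential decay of lifetime ``tau_ns``.

    ``g = 1/(1 + (omega tau)^2)``, ``s = omega tau/(1 + (omega tau)^2)``;
    the point lies exactly on the universal semicircle. ``tau_ns`` may be a
    scalar or an array.
    """
    tau = np.asarray(tau_ns, dtype=np.float64)
    if np.any(tau < 0) or not np.all(np.isfinite(tau)):
        raise ValueError("lifetime must be finite and >= 0")
    x = params.omega * tau
    denom = 1.0 + x * x
    g = 1.0 / denom
    s = x / denom
    if np.isscalar(tau_ns):
        return float(g), float(s)
    return g, s


def _aggregate_phase_modulation(
    counts: np.ndarray, params: AcquisitionParams
) -> tuple[float, float]:
    """Phase and modulation of the global summed decay of a stack."""
    total = counts.reshape(-1, counts.shape[-1]).sum(axis=0)
    intensity = total.sum()
    if intensity <= 0:
        raise ValueError("zero aggregate intensity in calibration reference")
    phases = params.omega * params.bin_times_ns
    g = float(total @ np.cos(phases) / intensity)
    s = float(total @ np.sin(phases) / intensity)
    return np.arctan2(s, g), float(np.hypot(g, s))


def compute_calibration(
    ref_stack: FlimStack,
    reference_lifetime_ns: float,
    params: AcquisitionParams,
    threshold: float | None = None,
) -> CalibrationTransform:
    """Derive the instrument calibration from a reference standard.

    The reference's aggregate phasor is the transform of the global summed
    decay of admitted pixels (equivalent to the intensity-weighted mean
    phasor, which is noise-optimal for Poisson counts). The returned
    transform maps it onto ``theoretical_phasor(reference_lifetime_ns)``:

        phase_offset  = phi_measured - phi_theory
        modulation_factor = m_theory / m_measured
    """
    if reference_lifetime_ns < 0:
        raise ValueError("reference lifetime must be >= 0")
    counts = ref_stack.counts
    if threshold is not None and threshold > 0:
        admitted = counts.sum(axis=2) >= threshold
        if not np.any(admitted):
            raise ValueError("no reference pixel reaches the intensity threshold")
        counts = counts[admitted]
    phi_meas, m_meas = _aggregate_phase_modulation(counts, params)
    if m_meas == 0:
        raise ValueError("reference aggregate modulation is zero")
    g_t, s_t = theoretical_phasor(reference_lifetime_ns, params)
    phi_t = float(np.arctan2(s_t, g_t))
    m_t = float(np.hypot(g_t, s_t))
    return CalibrationTransform(
        phase_offset_rad=phi_meas - phi_t,
        modulation_factor=m_t / m_meas,
        harmonic=params.harmonic,
        reference_lifetime_ns=float(reference_lifetime_ns),
    )


def _apply_polar(g, s, calib: CalibrationTransform):
    phi = np.arctan2(s, g) - calib.phase_offset_rad
    m = np.hypot(g, s) * calib.modulation_factor
    return m * np.cos(phi), m * np.sin(phi)


def apply_calibration(field: PhasorField, calib: CalibrationTransform) -> PhasorField:
    """Return a calibrated copy of ``field``; intensity is unchanged.

    The calibration must have been computed at the same harmonic, and a
    field cannot be calibrated twice.
    """
    if field.calibrated:
        raise ValueError("field is already calibrated")
    if calib.harmonic != field.params.harmonic:
        raise ValueError(
            f"calibration harmonic {calib.harmonic} does not match "
            f"field harmonic {field.params.harmonic}"
        )
    g, s = _apply_polar(field.g, field.s, calib)
    gu, su = _apply_polar(field.unfiltered_g, field.unfiltered_s, calib)
    return PhasorField(
        g=g,
        s=s,
        intensity=field.intensity.copy(),
        params=field.params,
        calibrated=True,
        median_passes_applied=field.median_passes_applied,
        unfiltered_g=gu,
        unfiltered_s=su,
    )


def lifetime_maps(field: PhasorField) -> LifetimeMaps:
    """Phase and modulation lifetime maps of a calibrated field.

    Policy for out-of-range phasors (noise can push pixels off the
    physical region): phase outside [0, pi/2) makes tau_phi NaN; modulation
    above 1 makes tau_M NaN; zero modulation makes both NaN. A pixel on
    the semicircle yields tau_phi == tau_M.
    """
    if not field.calibrated:
        raise ValueError("lifetime maps require a calibrated field")
    phi, m = phase_modulation(field)
    omega = field.params.omega
    with np.errstate(invalid="ignore", divide="ignore"):
        taup = np.tan(phi) / omega
        taum = np.sqrt(1.0 / (m * m) - 1.0) / omega
    bad_phase = ~((phi >= 0) & (phi < np.pi / 2))
    taup = np.where(bad_phase, np.nan, taup)
    taum = np.where(m > 1.0, np.nan, taum)
    zero_mod = m == 0
    taup = np.where(zero_mod, np.nan, taup)
    taum = np.where(zero_mod, np.nan, taum)
    return LifetimeMaps(taup_ns=taup, taum_ns=taum)
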