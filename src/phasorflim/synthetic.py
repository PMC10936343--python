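"""Synthetic FLIM stacks with known ground truth.

Emulates a time-correlated single-photon-counting acquisition over one
laser period: per-pixel expected decay histograms built from exact bin
integrals of (mixtures of) single exponentials, Poisson photon noise at a
programmed photon budget, and an optional instrument distortion expressed
as a phase offset plus modulation gain at the analysis harmonic — exactly
the model the phase/modulation calibration inverts. Defaults mirror a
typical two-photon FLIM regime: 80 MHz repetition rate, 56 temporal bins,
a few hundred photons per pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import write_stack
from .model import AcquisitionParams, FlimStack

__all__ = [
    "GroundTruth",
    "simulate_decay",
    "simulate_stack",
    "make_reference_stack",
    "write_fixture",
    "default_params",
]


def default_params(harmonic: int = 1) -> AcquisitionParams:
    """The emulated acquisition regime: 80 MHz, 56 bins over one period."""
    rep_rate_mhz = 80.0
    n_bins = 56
    bin_width_ns = 1.0 / (rep_rate_mhz * 1e-3 * n_bins)
    return AcquisitionParams(
        rep_rate_mhz=rep_rate_mhz,
        n_bins=n_bins,
        bin_width_ns=bin_width_ns,
        harmonic=harmonic,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a spatially uniform synthetic stack.

    ``components`` lists ``(lifetime_ns, intensity_fraction)`` pairs whose
    fractions sum to 1. ``instrument_phase_rad`` and
    ``instrument_modulation`` rotate and scale every pixel's underlying
    phasor at the analysis harmonic (gain in (0, 1] is typical of real
    detection chains). ``poisson_noise=False`` yields the noiseless
    expected histograms instead of Poisson draws.
    """

    components: tuple[tuple[float, float], ...] = ((2.0, 1.0),)
    photons_per_pixel: float = 500.0
    instrument_phase_rad: float = 0.0
    instrument_modulation: float = 1.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        comps = tuple((float(t), float(f)) for t, f in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("at least one decay component is required")
        if any(t < 0 for t, _ in comps):
            raise ValueError("lifetimes must be >= 0")
        if any(f < 0 for _, f in comps):
            raise ValueError("fractions must be >= 0")
        if abs(sum(f for _, f in comps) - 1.0) > 1e-9:
            raise ValueError("intensity fractions must sum to 1")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.instrument_modulation <= 0:
            raise ValueError("instrument_modulation must be positive")


def simulate_decay(
    components, params: AcquisitionParams, photons: float
) -> np.ndarray:
    """Expected counts per temporal bin for a decay mixture.

    Each component contributes exact bin integrals of its exponential,
    ``exp(-t_k/tau) - exp(-t_{k+1}/tau)`` (how TCSPC bins accumulate
    counts), normalized per component and mixed by intensity fraction; the
    total is scaled to ``photons``. A zero lifetime puts everything in bin
    0. Periodic re-excitation wrap-around is omitted: the steady-state
    wrapped decay is a scalar multiple of the single-period exponential
    and leaves the phasor unchanged.
    """
    comps = [(float(t), float(f)) for t, f in components]
    if abs(sum(f for _, f in comps) - 1.0) > 1e-9:
        raise ValueError("intensity fractions must sum to 1")
    if any(t < 0 or f < 0 for t, f in comps):
        raise ValueError("lifetimes and fractions must be >= 0")
    edges = np.arange(params.n_bins + 1) * params.bin_width_ns
    expected = np.zeros(params.n_bins)
    for tau, frac in comps:
        if frac == 0.0:
            continue
        if tau == 0.0:
            shape = np.zeros(params.n_bins)
            shape[0] = 1.0
        else:
            weights = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
            shape = weights / weights.sum()
        expected += frac * shape
    return photons * expected


def _harmonic_phasor(hist: np.ndarray, params: AcquisitionParams) -> complex:
    phases = params.omega * params.bin_times_ns
    return complex(np.sum(hist * np.exp(1j * phases)) / hist.sum())


def _distort_histogram(
    hist: np.ndarray,
    params: AcquisitionParams,
    phase_rad: float,
    modulation: float,
) -> np.ndarray:
    """Histogram with the same total whose phasor at the analysis harmonic
    is the original phasor rotated by ``phase_rad`` and scaled by
    ``modulation`` — exactly.

    Solved as a mixture ``w*hist + filler`` where the filler (a uniform
    component plus a pair of spikes in the two bins whose transform phases
    bracket the required correction) supplies the exact complex deficit at
    the harmonic. ``w`` is pushed as high as non-negativity allows via
    bisection, preserving as much of the true decay shape as possible.
    """
    if phase_rad == 0.0 and modulation == 1.0:
        return hist.copy()
    total = float(hist.sum())
    shape = hist / total
    p0 = _harmonic_phasor(shape, params)
    target = modulation * np.exp(1j * phase_rad) * p0

    phases = params.omega * params.bin_times_ns
    unit = np.exp(1j * phases)
    q = complex(unit.mean())  # phasor of the uniform filler

    def solve(w: float):
        """Filler masses (spike1, spike2, uniform) for decay weight w."""
        c = target - w * p0
        angle = np.angle(c)
        # two bins whose transform phases bracket angle (mod 2*pi)
        rel = np.mod(np.angle(unit) - angle, 2.0 * np.pi)
        below = np.where(rel > np.pi, rel - 2 * np.pi, rel)
        j1 = int(np.argmin(np.where(below <= 0, -below, np.inf)))
        j2 = int(np.argmin(np.where(below > 0, below, np.inf)))
        e1, e2 = unit[j1], unit[j2]
        mat = np.array(
            [
                [e1.real, e2.real, q.real],
                [e1.imag, e2.imag, q.imag],
                [1.0, 1.0, 1.0],
            ]
        )
        rhs = np.array([c.real, c.imag, 1.0 - w])
        try:
            masses = np.linalg.solve(mat, rhs)
        except np.linalg.LinAlgError:
            return None
        if np.any(masses < -1e-14):
            return None
        return j1, j2, np.maximum(masses, 0.0)

    if abs(target - p0) == 0.0:
        return hist.copy()
    if solve(0.0) is None:
        raise ValueError(
            "distortion target phasor is outside the attainable region "
            "of non-negative histograms"
        )
    lo, hi = 0.0, 1.0
    for _ in range(60):  # bisect for the largest feasible decay weight
        mid = 0.5 * (lo + hi)
        if solve(mid) is None:
            hi = mid
        else:
            lo = mid
    j1, j2, (m1, m2, beta) = solve(lo)
    out = lo * shape + beta / len(shape)
    out[j1] += m1
    out[j2] += m2
    return total * out


def simulate_stack(
    truth: GroundTruth, shape: tuple[int, int], params: AcquisitionParams
) -> FlimStack:
    """Simulate a stack of independent pixels sharing one ground truth.

    The expected histogram (distorted if the truth says so) is identical
    for every pixel; ``poisson_noise`` draws per-pixel Poisson counts
    around it from a single generator seeded with ``truth.seed``, so a
    fixed seed reproduces the stack bit-exactly.
    """
    rows, cols = shape
    expected = simulate_decay(truth.components, params, truth.photons_per_pixel)
    expected = _distort_histogram(
        expected, params, truth.instrument_phase_rad, truth.instrument_modulation
    )
    if truth.poisson_noise:
        rng = np.random.default_rng(truth.seed)
        counts = rng.poisson(
            np.broadcast_to(expected, (rows, cols, params.n_bins))
        ).astype(np.float64)
    else:
        counts = np.tile(expected, (rows, cols, 1))
    return FlimStack(counts=counts, source_path=f"synthetic(seed={truth.seed})")


def make_reference_stack(
    tau_ref_ns: float,
    params: AcquisitionParams,
    shape: tuple[int, int] = (16, 16),
    photons_per_pixel: float = 5000.0,
    instrument_phase_rad: float = 0.0,
    instrument_modulation: float = 1.0,
    poisson_noise: bool = False,
    seed: int = 0,
) -> FlimStack:
    """Spatially uniform calibration-standard stack at ``tau_ref_ns``.

    Defaults are noiseless with a generous photon budget, as a calibration
    measurement would be; the distortion model is the same as for sample
    stacks so that distorted data can be calibrated with an identically
    distorted reference.
    """
    truth = GroundTruth(
        components=((float(tau_ref_ns), 1.0),),
        photons_per_pixel=photons_per_pixel,
        instrument_phase_rad=instrument_phase_rad,
        instrument_modulation=instrument_modulation,
        poisson_noise=poisson_noise,
        seed=seed,
    )
    return simulate_stack(truth, shape, params)


def write_fixture(
    stack: FlimStack, truth: GroundTruth, path: str | Path
) -> tuple[Path, Path]:
    """Write a stack as TIFF plus its ground truth as a JSON sidecar."""
    path = Path(path)
    write_stack(stack, path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(asdict(truth), indent=2) + "\n")
    return path, sidecar
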