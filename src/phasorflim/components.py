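"""Molecular-species geometry in phasor space.

A species is a fixed point in the phasor plane: on the universal
semicircle when defined by a single lifetime, or anywhere inside the unit
square when placed explicitly (multi-exponential species). Contrast maps
derive from it: the Euclidean distance of every pixel's phasor from a
species B, and the two-component fraction of species A obtained by
normalizing against the A-B separation. Cursor masks implement the
reciprocity principle: select a disk in phasor space, highlight the image
pixels whose phasors fall inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filtering import Mask
from .io import AnalysisResult, SummaryStats
from .model import AcquisitionParams
from .phasor import PhasorField, theoretical_phasor

__all__ = [
    "SpeciesLocation",
    "DistanceMap",
    "FractionMap",
    "species_from_lifetime",
    "species_at",
    "distance_map",
    "fraction_map",
    "cursor_mask",
    "roi_statistics",
]

_SEMICIRCLE_S_MAX = 0.5 + 1e-9


@dataclass(frozen=True)
class SpeciesLocation:
    """A named point in phasor space.

    ``origin`` records whether the point came from a single lifetime (it
    then lies on the universal semicircle) or was placed explicitly.
    """

    name: str
    g: float
    s: float
    origin: str = "explicit"
    tau_ns: float | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("from_lifetime", "explicit"):
            raise ValueError("origin must be 'from_lifetime' or 'explicit'")
        if self.origin == "from_lifetime":
            if not (0.0 <= self.g <= 1.0 and 0.0 <= self.s <= _SEMICIRCLE_S_MAX):
                raise ValueError(
                    f"species {self.name!r}: lifetime-derived location "
                    f"({self.g}, {self.s}) is off the universal semicircle"
                )


@dataclass(frozen=True)
class DistanceMap:
    """Per-pixel Euclidean phasor distance from a reference species B."""

    d: np.ndarray
    species: SpeciesLocation


@dataclass(frozen=True)
class FractionMap:
    """Per-pixel fractional contribution of species A in an A/B mixture.

    0 at B's location, 1 at A's; values outside [0, 1] can occur for
    pixels off the A-B segment unless clipping was requested.
    """

    f_a: np.ndarray
    species_a: SpeciesLocation
    species_b: SpeciesLocation


def species_from_lifetime(
    name: str, tau_ns: float, params: AcquisitionParams
) -> SpeciesLocation:
    """Place a species on the universal semicircle from its lifetime."""
    g, s = theoretical_phasor(tau_ns, params)
    return SpeciesLocation(name=name, g=g, s=s, origin="from_lifetime", tau_ns=tau_ns)


def species_at(name: str, g: float, s: float) -> SpeciesLocation:
    """Place a species at explicit phasor coordinates."""
    return SpeciesLocation(name=name, g=float(g), s=float(s), origin="explicit")


def distance_map(field: PhasorField, species_b: SpeciesLocation) -> DistanceMap:
    """Euclidean distance of every pixel's phasor from species B.

    Requires a calibrated field; undefined pixels stay undefined.
    """
    if not field.calibrated:
        raise ValueError("distance map requires a calibrated field")
    d = np.hypot(field.g - species_b.g, field.s - species_b.s)
    return DistanceMap(d=d, species=species_b)


def fraction_map(
    field: PhasorField,
    species_a: SpeciesLocation,
    species_b: SpeciesLocation,
    clip: bool = False,
) -> FractionMap:
    """Fraction of species A per pixel in a two-component A/B system.

    For a non-interacting mixture the pixel phasor is the intensity-
    weighted combination ``f_A * A + (1 - f_A) * B``, so f_A is recovered
    as the scalar projection of (phasor - B) onto the unit B->A direction,
    normalized by the A-B separation. On the A-B segment this equals the
    distance-from-B divided by |AB|; off the segment the signed projection
    is reported (and can leave [0, 1]) unless ``clip`` is set. The
    fraction is intensity-weighted, not quantum-yield-weighted.
    """
    if not field.calibrated:
        raise ValueError("fraction map requires a calibrated field")
    dg = species_a.g - species_b.g
    ds = species_a.s - species_b.s
    sep_sq = dg * dg + ds * ds
    if sep_sq <= 1e-18:
        raise ValueError(
            f"species {species_a.name!r} and {species_b.name!r} coincide"
        )
    f_a = ((field.g - species_b.g) * dg + (field.s - species_b.s) * ds) / sep_sq
    if clip:
        f_a = np.clip(f_a, 0.0, 1.0)
    return FractionMap(f_a=f_a, species_a=species_a, species_b=species_b)


def cursor_mask(
    field: PhasorField, center_g: float, center_s: float, radius: float
) -> Mask:
    """Pixels whose phasor lies within a closed disk in phasor space."""
    if radius <= 0:
        raise ValueError("cursor radius must be positive")
    dist_sq = (field.g - center_g) ** 2 + (field.s - center_s) ** 2
    with np.errstate(invalid="ignore"):
        include = np.isfinite(dist_sq) & (dist_sq <= radius * radius)
    return Mask(
        include,
        [(f"cursor(g={center_g:g}, s={center_s:g})", 0.0, float(radius))],
    )


def roi_statistics(result: AnalysisResult, mask: Mask) -> SummaryStats:
    """Unweighted means of g, s, TauP, TauM (and distance when present)
    over the pixels admitted by both the result's own mask and ``mask``.

    NaN entries are excluded per-statistic; an empty selection is an error.
    """
    if mask.include.shape != result.g_map.shape:
        raise ValueError("mask dimensions do not match the result")
    return result.masked_means(include=mask.include)
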