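"""Reversible spatial filtering and mask construction.

The only spatial filter is the 3x3 median applied to the phasor g and s
coordinates (never to the intensity), optionally repeated. It is
"reversible" in the workflow sense: the pristine coordinates are retained
on the field and :func:`revert_filters` restores them bit-exactly.
Masks select pixels by intensity, by a contrast range on any derived map,
or by conjunction of several criteria; all bounds are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .phasor import PhasorField

__all__ = [
    "Mask",
    "intensity_mask",
    "median_filter_phasor",
    "revert_filters",
    "contrast_mask",
    "combine_masks",
]


@dataclass
class Mask:
    """Boolean pixel-inclusion grid with a provenance trail.

    ``provenance`` is an ordered list of ``(criterion, lo, hi)`` records;
    a pixel is included iff it passed every recorded criterion.
    """

    include: np.ndarray
    provenance: list[tuple[str, float, float]] = dataclass_field(default_factory=list)

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)

    @property
    def n_included(self) -> int:
        return int(self.include.sum())

    @classmethod
    def all_true(cls, shape: tuple[int, int]) -> "Mask":
        return cls(np.ones(shape, dtype=bool))

    def describe(self) -> list[str]:
        """Human-readable provenance lines for the analysis log."""
        return [
            f"mask: {name} in [{lo:g}, {hi:g}]" for name, lo, hi in self.provenance
        ]


def intensity_mask(
    field: PhasorField, min_counts: float, max_counts: float | None = None
) -> Mask:
    """Mask of pixels whose total counts lie in ``[min_counts, max_counts]``."""
    if min_counts < 0:
        raise ValueError("min_counts must be >= 0")
    if max_counts is not None and max_counts <= min_counts:
        raise ValueError("max_counts must exceed min_counts")
    include = field.intensity >= min_counts
    hi = np.inf if max_counts is None else float(max_counts)
    if max_counts is not None:
        include &= field.intensity <= max_counts
    return Mask(include, [("intensity", float(min_counts), hi)])


def _median3x3_nan(a: np.ndarray) -> np.ndarray:
    """3x3 sliding-window median with reflect padding.

    NaN neighbors are excluded from each window; a pixel that is itself
    NaN stays NaN.
    """
    padded = np.pad(a, 1, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        out = np.nanmedian(windows, axis=(2, 3))
    out[np.isnan(a)] = np.nan
    return out


def median_filter_phasor(field: PhasorField, passes: int) -> PhasorField:
    """Apply ``passes`` rounds of the 3x3 median to g and s.

    Intensity is untouched and the pristine coordinates are carried along
    so the operation can be reverted.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    g, s = field.g, field.s
    for _ in range(passes):
        g = _median3x3_nan(g)
        s = _median3x3_nan(s)
    return PhasorField(
        g=g,
        s=s,
        intensity=field.intensity,
        params=field.params,
        calibrated=field.calibrated,
        median_passes_applied=field.median_passes_applied + passes,
        unfiltered_g=field.unfiltered_g,
        unfiltered_s=field.unfiltered_s,
    )


def revert_filters(field: PhasorField) -> PhasorField:
    """Restore the pristine (unfiltered) g and s coordinates."""
    return PhasorField(
        g=field.unfiltered_g.copy(),
        s=field.unfiltered_s.copy(),
        intensity=field.intensity,
        params=field.params,
        calibrated=field.calibrated,
        median_passes_applied=0,
        unfiltered_g=field.unfiltered_g,
        unfiltered_s=field.unfiltered_s,
    )


def contrast_mask(
    map_values: np.ndarray, lo: float, hi: float, name: str = "contrast"
) -> Mask:
    """Mask of defined pixels whose map value lies in ``[lo, hi]``."""
    if lo > hi:
        raise ValueError("lower bound exceeds upper bound")
    defined = np.isfinite(map_values)
    with np.errstate(invalid="ignore"):
        include = defined & (map_values >= lo) & (map_values <= hi)
    return Mask(include, [(name, float(lo), float(hi))])


def combine_masks(a: Mask, b: Mask) -> Mask:
    """Logical AND of two masks; provenance is concatenated."""
    if a.include.shape != b.include.shape:
        raise ValueError("masks have different dimensions")
    return Mask(a.include & b.include, list(a.provenance) + list(b.provenance))
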