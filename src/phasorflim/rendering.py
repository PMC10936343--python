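"""Non-interactive figure export: phasor density plots and contrast maps.

Everything renders through the Agg backend to PNG with a pinned figure
geometry, so output bytes are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless by design

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LogNorm

from .filtering import Mask
from .phasor import PhasorField

__all__ = [
    "PhasorHistogram",
    "phasor_histogram",
    "render_phasor_plot",
    "render_map",
    "PHASOR_DOMAIN",
]

#: Default histogram domain: ((g_min, g_max), (s_min, s_max)), slightly
#: padded around the physical region so semicircle points land in bins.
PHASOR_DOMAIN = ((-0.005, 1.005), (-0.005, 0.605))

_FIG_DPI = 150


@dataclass(frozen=True)
class PhasorHistogram:
    """2-D density histogram of (g, s) pairs.

    ``n_defined`` counts the pairs actually binned; pairs outside the
    domain are dropped, so ``counts.sum() == n_defined`` always holds.
    """

    counts: np.ndarray
    g_edges: np.ndarray
    s_edges: np.ndarray
    n_defined: int


def phasor_histogram(
    field: PhasorField, mask: Mask | None = None, bins: int = 200
) -> PhasorHistogram:
    """Histogram the defined, mask-included phasor coordinates.

    Bins are half-open with the last bin closed (numpy convention).
    """
    if bins < 10:
        raise ValueError("bins must be >= 10")
    select = np.isfinite(field.g) & np.isfinite(field.s)
    if mask is not None:
        if mask.include.shape != field.shape:
            raise ValueError("mask dimensions do not match the field")
        select &= mask.include
    g = field.g[select]
    s = field.s[select]
    if g.size == 0:
        raise ValueError("no defined pixels to histogram")
    counts, g_edges, s_edges = np.histogram2d(
        g, s, bins=bins, range=PHASOR_DOMAIN
    )
    counts = counts.astype(np.int64)
    return PhasorHistogram(
        counts=counts,
        g_edges=g_edges,
        s_edges=s_edges,
        n_defined=int(counts.sum()),
    )


def _draw_universal_semicircle(ax) -> None:
    theta = np.linspace(0.0, np.pi, 400)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "k-", lw=1)


def render_phasor_plot(
    hist: PhasorHistogram,
    out_path: str | Path,
    overlays=(),
    cursors=(),
    harmonic: int | None = None,
    log_scale: bool = True,
) -> Path:
    """Render a phasor density plot with the universal semicircle.

    ``overlays`` are species locations (marked and labelled); ``cursors``
    are ``(g, s, radius)`` circles. The harmonic, when given, is annotated
    in the top corner.
    """
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(6, 4.2), dpi=_FIG_DPI)
    masked = np.ma.masked_equal(hist.counts.T, 0)
    norm = LogNorm(vmin=1, vmax=max(1, hist.counts.max())) if log_scale else None
    mesh = ax.pcolormesh(
        hist.g_edges, hist.s_edges, masked, cmap="nipy_spectral", norm=norm
    )
    fig.colorbar(mesh, ax=ax, label="pixels per bin")
    _draw_universal_semicircle(ax)
    for species in overlays:
        ax.plot(species.g, species.s, "o", ms=6, mfc="white", mec="black")
        ax.annotate(species.name, (species.g, species.s), fontsize=8,
                    xytext=(4, 4), textcoords="offset points")
    for cg, cs, radius in cursors:
        ax.add_patch(
            plt.Circle((cg, cs), radius, fill=False, ec="red", lw=1.2)
        )
    if harmonic is not None:
        ax.text(
            0.98, 0.95, f"harmonic {harmonic}", transform=ax.transAxes,
            ha="right", va="top", fontsize=9,
        )
    ax.set_xlim(hist.g_edges[0], hist.g_edges[-1])
    ax.set_ylim(hist.s_edges[0], hist.s_edges[-1])
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_aspect("equal")
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def render_map(
    map_values: np.ndarray,
    out_path: str | Path,
    lo: float,
    hi: float,
    colormap_name: str = "viridis",
) -> Path:
    """Render a contrast map clamped to [lo, hi]; NaN pixels are black."""
    if lo >= hi:
        raise ValueError("lo must be smaller than hi")
    out_path = Path(out_path)
    cmap = plt.get_cmap(colormap_name).copy()
    cmap.set_bad("black")
    fig, ax = plt.subplots(figsize=(6, 4.8), dpi=_FIG_DPI)
    image = ax.imshow(
        map_values, cmap=cmap, vmin=lo, vmax=hi, interpolation="nearest"
    )
    fig.colorbar(image, ax=ax)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
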