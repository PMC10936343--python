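"""Reading FLIM TIFF stacks, writing result maps, and run configuration.

Input stacks are multi-page grayscale TIFFs, one temporal bin per page.
Result maps are exported as single-page 32-bit float TIFFs with NaN marking
masked/undefined pixels (ImageJ-compatible), next to a CSV summary row and
a plain-text provenance log.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .model import AcquisitionParams, FlimStack
from .phasor import CalibrationTransform

__all__ = [
    "AcquisitionParams",
    "FlimStack",
    "AnalysisResult",
    "SummaryStats",
    "RunConfig",
    "read_flim_stack",
    "write_stack",
    "write_result",
    "load_run_config",
    "SUMMARY_COLUMNS",
]

#: Fixed column order of the summary CSV.
SUMMARY_COLUMNS = (
    "file",
    "n_pixels",
    "mean_g",
    "mean_s",
    "mean_taup_ns",
    "mean_taum_ns",
    "mean_distance",
)

#: Tolerance for accepting float-typed TIFF pages as photon counts.
_INTEGRAL_ATOL = 1e-6


@dataclass(frozen=True)
class SummaryStats:
    """Unweighted means over the included, defined pixels of a result."""

    mean_g: float
    mean_s: float
    mean_taup_ns: float
    mean_taum_ns: float
    mean_distance: float | None
    n_pixels: int


@dataclass
class AnalysisResult:
    """All per-pixel maps of one analyzed image plus provenance.

    Maps share dimensions; NaN marks undefined pixels. ``mask`` selects the
    pixels admitted by the applied thresholds: masked-out pixels are
    excluded from summary statistics and written as NaN in exported maps.
    """

    g_map: np.ndarray
    s_map: np.ndarray
    intensity_map: np.ndarray
    taup_map: np.ndarray
    taum_map: np.ndarray
    mask: np.ndarray
    params: AcquisitionParams
    calibration: CalibrationTransform
    distance_map: np.ndarray | None = None
    fraction_map: np.ndarray | None = None
    provenance: list[str] = dataclass_field(default_factory=list)
    source: str = "<memory>"

    def __post_init__(self) -> None:
        shape = self.g_map.shape
        for name in ("s_map", "intensity_map", "taup_map", "taum_map", "mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} does not match map dimensions {shape}")
        for name in ("distance_map", "fraction_map"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != shape:
                raise ValueError(f"{name} does not match map dimensions {shape}")
        self.mask = np.asarray(self.mask, dtype=bool)

    def masked_means(self, include: np.ndarray | None = None) -> SummaryStats:
        """Summary statistics over ``mask`` (optionally ANDed with ``include``)."""
        selected = self.mask if include is None else (self.mask & include)
        n = int(selected.sum())
        if n == 0:
            raise ValueError("no pixels selected")

        def mean_of(arr: np.ndarray) -> float:
            values = arr[selected]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return float(np.nanmean(values))

        return SummaryStats(
            mean_g=mean_of(self.g_map),
            mean_s=mean_of(self.s_map),
            mean_taup_ns=mean_of(self.taup_map),
            mean_taum_ns=mean_of(self.taum_map),
            mean_distance=(
                mean_of(self.distance_map) if self.distance_map is not None else None
            ),
            n_pixels=n,
        )


def read_flim_stack(path: str | Path) -> FlimStack:
    """Read a multi-page TIFF stack; page order is temporal bin order.

    Pages must share dimensions; pixel values must be non-negative and,
    for float-typed files, integral within 1e-6 (some exporters save
    counts as float).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FLIM stack: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        n_pages = len(pages)
        if n_pages < 2:
            raise ValueError(f"{path.name}: fewer than 2 temporal bins")
        shape0 = pages[0].shape
        arrays = []
        for k, page in enumerate(pages):
            if page.shape != shape0:
                raise ValueError(
                    f"{path.name}: page {k} has shape {page.shape}, "
                    f"expected {shape0}"
                )
            arr = page.asarray()
            if np.any(arr < 0):
                raise ValueError(f"{path.name}: negative values on page {k}")
            if np.issubdtype(arr.dtype, np.floating):
                if np.max(np.abs(arr - np.round(arr))) > _INTEGRAL_ATOL:
                    raise ValueError(
                        f"{path.name}: page {k} has non-integral float counts"
                    )
                arr = np.round(arr)
            arrays.append(np.asarray(arr, dtype=np.float64))
    counts = np.stack(arrays, axis=-1)
    return FlimStack(counts=counts, source_path=str(path))


def write_stack(stack: FlimStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF, one temporal bin per page.

    Integer-valued counts are stored with the smallest sufficient unsigned
    integer type so that ``read_flim_stack(write_stack(x)) == x``.
    """
    path = Path(path)
    pages = np.moveaxis(stack.counts, -1, 0)
    if np.all(pages == np.round(pages)):
        dtype = np.uint16 if pages.max(initial=0) < 2**16 else np.uint32
        pages = pages.astype(dtype)
    else:
        pages = pages.astype(np.float32)
    # one grayscale page per temporal bin (never RGB planes)
    tifffile.imwrite(path, pages, photometric="minisblack")
    return path


def _write_float_map(arr: np.ndarray, mask: np.ndarray, path: Path) -> Path:
    out = np.asarray(arr, dtype=np.float32).copy()
    out[~mask] = np.nan
    tifffile.imwrite(path, out)
    return path


def write_result(result: AnalysisResult, out_dir: str | Path) -> list[Path]:
    """Export one result: float TIFF per map, a CSV summary row, a log.

    The distance map TIFF and its CSV column are present only when the
    result carries a distance map; the same holds for the fraction map
    (which has no CSV column).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    written: list[Path] = []
    maps = {
        "g": result.g_map,
        "s": result.s_map,
        "intensity": result.intensity_map,
        "taup": result.taup_map,
        "taum": result.taum_map,
    }
    if result.distance_map is not None:
        maps["distance"] = result.distance_map
    if result.fraction_map is not None:
        maps["fraction"] = result.fraction_map
    for name, arr in maps.items():
        written.append(_write_float_map(arr, result.mask, out_dir / f"{name}.tif"))

    stats = result.masked_means()
    csv_path = out_dir / "summary.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        writer.writerow(summary_row(result.source, stats))
    written.append(csv_path)

    log_path = out_dir / "provenance.log"
    lines = [
        f"source: {result.source}",
        f"rep_rate_mhz: {result.params.rep_rate_mhz}",
        f"n_bins: {result.params.n_bins}",
        f"bin_width_ns: {result.params.bin_width_ns}",
        f"harmonic: {result.params.harmonic}",
        f"calibration: phase_offset_rad={result.calibration.phase_offset_rad!r} "
        f"modulation_factor={result.calibration.modulation_factor!r} "
        f"reference_lifetime_ns={result.calibration.reference_lifetime_ns!r}",
        *result.provenance,
    ]
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)
    return written


def summary_row(source: str, stats: SummaryStats) -> list:
    """One CSV row in the fixed :data:`SUMMARY_COLUMNS` order."""
    return [
        source,
        stats.n_pixels,
        repr(stats.mean_g),
        repr(stats.mean_s),
        repr(stats.mean_taup_ns),
        repr(stats.mean_taum_ns),
        "" if stats.mean_distance is None else repr(stats.mean_distance),
    ]


# --------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Validated analysis configuration with explicit defaults.

    Calibration is specified either by a reference stack path plus its
    known lifetime, or by an explicit phase offset / modulation factor —
    never both.
    """

    params: AcquisitionParams
    reference_path: str | None = None
    reference_lifetime_ns: float | None = None
    phase_offset_rad: float | None = None
    modulation_factor: float | None = None
    min_intensity: float = 0.0
    max_intensity: float | None = None
    median_passes: int = 0
    species: list[dict] = dataclass_field(default_factory=list)
    output_dir: str = "."
    inputs: list[str] = dataclass_field(default_factory=list)

    @property
    def has_explicit_calibration(self) -> bool:
        return self.phase_offset_rad is not None or self.modulation_factor is not None


_MANDATORY_KEYS = ("rep_rate_mhz", "n_bins", "bin_width_ns")
_KNOWN_TOP = set(_MANDATORY_KEYS) | {
    "harmonic",
    "calibration",
    "filters",
    "species",
    "output_dir",
    "inputs",
}
_KNOWN_CALIBRATION = {
    "reference",
    "reference_lifetime_ns",
    "phase_offset_rad",
    "modulation_factor",
}
_KNOWN_FILTERS = {"min_intensity", "max_intensity", "median_passes"}


def _warn_unknown(keys, known, context: str) -> None:
    for key in keys:
        if key not in known:
            warnings.warn(f"unknown config key {context}{key!r} ignored", stacklevel=3)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:  # YAML is a superset of JSON, so this also accepts .yaml/.yml/other
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path.name}: config must be a mapping")

    missing = [k for k in _MANDATORY_KEYS if k not in raw]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory keys {missing}")
    _warn_unknown(raw, _KNOWN_TOP, "")

    params = AcquisitionParams(
        rep_rate_mhz=float(raw["rep_rate_mhz"]),
        n_bins=int(raw["n_bins"]),
        bin_width_ns=float(raw["bin_width_ns"]),
        harmonic=int(raw.get("harmonic", 1)),
    )

    cfg = RunConfig(params=params)
    calibration = raw.get("calibration") or {}
    _warn_unknown(calibration, _KNOWN_CALIBRATION, "calibration.")
    has_reference = "reference" in calibration
    has_explicit = (
        "phase_offset_rad" in calibration or "modulation_factor" in calibration
    )
    if has_reference and has_explicit:
        raise ValueError("calibration over-specified: give a reference or explicit factors, not both")
    if has_reference:
        cfg.reference_path = str(calibration["reference"])
        if "reference_lifetime_ns" not in calibration:
            raise ValueError("calibration reference requires reference_lifetime_ns")
        cfg.reference_lifetime_ns = float(calibration["reference_lifetime_ns"])
    elif has_explicit:
        cfg.phase_offset_rad = float(calibration.get("phase_offset_rad", 0.0))
        cfg.modulation_factor = float(calibration.get("modulation_factor", 1.0))

    filters = raw.get("filters") or {}
    _warn_unknown(filters, _KNOWN_FILTERS, "filters.")
    cfg.min_intensity = float(filters.get("min_intensity", 0.0))
    if filters.get("max_intensity") is not None:
        cfg.max_intensity = float(filters["max_intensity"])
    cfg.median_passes = int(filters.get("median_passes", 0))
    if cfg.median_passes < 0:
        raise ValueError("median_passes must be >= 0")

    for spec in raw.get("species") or []:
        if "name" not in spec:
            raise ValueError("each species needs a name")
        if ("tau_ns" in spec) == ("g" in spec or "s" in spec):
            raise ValueError(
                f"species {spec.get('name')!r}: give either tau_ns or explicit g, s"
            )
        cfg.species.append(dict(spec))

    cfg.output_dir = str(raw.get("output_dir", "."))
    inputs = raw.get("inputs") or []
    cfg.inputs = [str(p) for p in inputs]
    return cfg
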