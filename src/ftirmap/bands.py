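"""Band intensity/integral extraction, ratios, and chemical-map rendering.

Peak intensity is read as the local maximum inside ``center +/-
peak_window`` (one nominal resolution element by default), which tolerates
small peak shifts; with ``peak_window=0`` the nearest-channel value is used.
Integrals are plain trapezoids over the band's integral range with no local
baseline subtraction.
"""

from __future__ import annotations

import json
import warnings

import numpy as np

from .core import (
    BandDef,
    OutOfRangeError,
    PixelMask,
    SpectralCube,
    WavenumberAxis,
    nearest_channel,
)

__all__ = [
    "DEFAULT_BANDS",
    "band_intensity",
    "band_integral",
    "band_ratio",
    "chemical_map",
    "band_intensity_map",
    "load_band_table",
    "dump_band_table",
]

# Conventional SC-relevant bands; integral windows are exposed, not fixed by theory.
DEFAULT_BANDS: dict[str, BandDef] = {
    "amide2": BandDef("amide2", 1548.0, 8.0, (1500.0, 1590.0)),
    "amide1": BandDef("amide1", 1652.0, 8.0, (1600.0, 1700.0)),
    "ch2_sym": BandDef("ch2_sym", 2850.0, 8.0, (2830.0, 2870.0)),
    "ch2_asym": BandDef("ch2_asym", 2920.0, 8.0, (2890.0, 2950.0)),
}


def _window_slice(axis: WavenumberAxis, lo: float, hi: float) -> slice:
    idx = np.nonzero((axis.values >= lo) & (axis.values <= hi))[0]
    if idx.size == 0:
        raise OutOfRangeError(f"no channels inside [{lo}, {hi}] cm^-1")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def band_intensity(spectrum: np.ndarray, axis: WavenumberAxis, band: BandDef) -> float:
    """Peak absorbance of ``band``; NaN if every channel in the window is NaN."""
    spectrum = np.asarray(spectrum, dtype=float)
    if not (axis.lo <= band.center <= axis.hi):
        raise OutOfRangeError(f"band center {band.center} outside axis")
    if band.peak_window == 0:
        return float(spectrum[nearest_channel(axis, band.center)])
    window = spectrum[_window_slice(axis, band.center - band.peak_window, band.center + band.peak_window)]
    if np.all(np.isnan(window)):
        return float("nan")
    return float(np.nanmax(window))


def band_integral(spectrum: np.ndarray, axis: WavenumberAxis, band: BandDef) -> float:
    """Trapezoidal integral of absorbance over the band's integral range."""
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = band.integral_range
    if not axis.covers(lo, hi):
        raise OutOfRangeError(f"integral range [{lo}, {hi}] outside axis")
    sl = _window_slice(axis, lo, hi)
    return float(np.trapezoid(spectrum[sl], axis.values[sl]))


def band_ratio(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    numerator: BandDef,
    denominator: BandDef,
) -> float:
    """Intensity ratio of two bands; NaN propagates, zero denominator yields NaN."""
    num = band_intensity(spectrum, axis, numerator)
    den = band_intensity(spectrum, axis, denominator)
    if not np.isfinite(num) or not np.isfinite(den) or den == 0:
        return float("nan")
    return num / den


def band_intensity_map(cube: SpectralCube, band: BandDef) -> np.ndarray:
    """Vectorised per-pixel :func:`band_intensity` over a cube."""
    if not (cube.axis.lo <= band.center <= cube.axis.hi):
        raise OutOfRangeError(f"band center {band.center} outside axis")
    if band.peak_window == 0:
        return cube.data[..., nearest_channel(cube.axis, band.center)].copy()
    sl = _window_slice(cube.axis, band.center - band.peak_window, band.center + band.peak_window)
    window = cube.data[..., sl]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows -> NaN
        return np.nanmax(window, axis=-1)


def chemical_map(cube: SpectralCube, band: BandDef | None = None, mode: str = "intensity") -> np.ndarray:
    """Per-pixel scalar grid for a band (or the whole axis for ``mode='total'``).

    Modes: ``intensity`` (windowed peak maximum), ``integral`` (trapezoid over
    the band's integral range), ``total`` (trapezoid over all channels,
    ignoring ``band``).  Invalid (all-NaN) pixels come out as NaN.
    """
    if mode == "total":
        return np.trapezoid(cube.data, cube.axis.values, axis=-1)
    if band is None:
        raise OutOfRangeError("band required for intensity/integral modes")
    if mode == "intensity":
        return band_intensity_map(cube, band)
    if mode == "integral":
        lo, hi = band.integral_range
        if not cube.axis.covers(lo, hi):
            raise OutOfRangeError(f"integral range [{lo}, {hi}] outside axis")
        sl = _window_slice(cube.axis, lo, hi)
        return np.trapezoid(cube.data[..., sl], cube.axis.values[sl], axis=-1)
    raise ValueError(f"unknown mode {mode!r}")


def invalid_pixels(values: np.ndarray, provenance: str = "invalid") -> PixelMask:
    """Mask that is False where a per-pixel value grid is non-finite."""
    return PixelMask(np.isfinite(np.asarray(values)), provenance)


def load_band_table(path) -> dict[str, BandDef]:
    """Load band definitions from a JSON table ``{name: {center, peak_window, integral_range}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    table = {}
    for name, spec in raw.items():
        table[name] = BandDef(
            name=name,
            center=float(spec["center"]),
            peak_window=float(spec.get("peak_window", 8.0)),
            integral_range=tuple(spec.get("integral_range", (0.0, 0.0))),
        )
    return table


def dump_band_table(path, table: dict[str, BandDef]) -> None:
    raw = {
        name: {
            "center": band.center,
            "peak_window": band.peak_window,
            "integral_range": list(band.integral_range),
        }
        for name, band in table.items()
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)
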