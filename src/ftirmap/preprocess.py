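"""Per-spectrum baseline correction and normalization, composable into plans.

Baseline correction follows the modified-polyfit family: fit a polynomial,
clip the spectrum to the fit wherever it lies above it, refit, and stop when
the fit settles (max relative change below ``tol``) or ``max_iter`` is hit.
The final fit is subtracted; negative absorbance is deliberately not
clipped.

A :class:`PreprocessPlan` applies baseline correction first, then one of
three normalizations: none, division by the Amide II peak intensity, or
division by the spectrum's mean over the whole stored axis ("area").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bands as _bands
from .core import (
    BandDef,
    DegenerateInputError,
    DomainError,
    NormalizationError,
    PixelMask,
    SpectralCube,
    WavenumberAxis,
)

__all__ = [
    "BaselineParams",
    "PreprocessPlan",
    "baseline_correct",
    "normalize_area",
    "normalize_amide2",
    "apply_plan",
    "six_scenarios",
]

NORMALIZATIONS = ("none", "amide2", "area")


@dataclass(frozen=True)
class BaselineParams:
    order: int = 2
    max_iter: int = 100
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.order < 0:
            raise DomainError("polynomial order must be >= 0")
        if self.max_iter < 1:
            raise DomainError("max_iter must be >= 1")
        if self.tol <= 0:
            raise DomainError("tol must be positive")


@dataclass(frozen=True)
class PreprocessPlan:
    """Baseline step (or None) plus a normalization choice."""

    baseline: BaselineParams | None = None
    normalization: str = "none"
    amide2_band: BandDef = field(default_factory=lambda: _bands.DEFAULT_BANDS["amide2"])

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise DomainError(f"normalization must be one of {NORMALIZATIONS}")

    def describe(self) -> str:
        base = "none" if self.baseline is None else (
            f"iterative_poly(order={self.baseline.order},max_iter={self.baseline.max_iter},tol={self.baseline.tol})"
        )
        return f"baseline={base};normalization={self.normalization}"


def _design(n: int, order: int) -> np.ndarray:
    # index-based abscissa scaled to [-1, 1] for conditioning; equivalent to
    # fitting in wavenumber on a uniform axis
    x = np.linspace(-1.0, 1.0, n)
    return np.vander(x, order + 1, increasing=True)


def _iterate_fit(y: np.ndarray, design: np.ndarray, pinv: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    """Clip-above-fit iteration for one spectrum; returns the final fit."""
    work = y.copy()
    scale = float(np.ptp(y))
    if scale == 0:
        return np.zeros_like(y)
    fit = design @ (pinv @ work)
    for _ in range(max_iter - 1):
        work = np.minimum(work, fit)
        new_fit = design @ (pinv @ work)
        if np.max(np.abs(new_fit - fit)) < tol * scale:
            fit = new_fit
            break
        fit = new_fit
    return fit


def baseline_correct(
    spectrum: np.ndarray,
    order: int = 2,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> np.ndarray:
    """Subtract an iteratively fitted polynomial baseline from one spectrum.

    NaN channels are excluded from the fit and passed through unchanged.
    """
    params = BaselineParams(order=order, max_iter=max_iter, tol=tol)
    spectrum = np.asarray(spectrum, dtype=float)
    finite = np.isfinite(spectrum)
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise DegenerateInputError("spectrum has no finite channels")
    if n_finite <= params.order + 1:
        raise DegenerateInputError(
            f"need more than order+1={params.order + 1} finite channels, got {n_finite}"
        )
    design_full = _design(spectrum.size, params.order)
    if n_finite == spectrum.size:
        design = design_full
    else:
        design = design_full[finite]
    pinv = np.linalg.pinv(design)
    fit_finite = _iterate_fit(spectrum[finite], design, pinv, params.max_iter, params.tol)
    corrected = spectrum.copy()
    corrected[finite] = spectrum[finite] - fit_finite
    return corrected


def _baseline_correct_block(block: np.ndarray, params: BaselineParams) -> np.ndarray:
    """Vectorised clip-above-fit over fully finite spectra, shape (n, channels)."""
    n, n_channels = block.shape
    design = _design(n_channels, params.order)
    pinv = np.linalg.pinv(design)
    work = block.T.copy()  # (channels, n)
    scale = np.ptp(block, axis=1)  # (n,)
    fit = design @ (pinv @ work)
    active = np.nonzero(scale > 0)[0]
    for _ in range(params.max_iter - 1):
        if active.size == 0:
            break
        work[:, active] = np.minimum(work[:, active], fit[:, active])
        new_fit = design @ (pinv @ work[:, active])
        delta = np.max(np.abs(new_fit - fit[:, active]), axis=0) / scale[active]
        fit[:, active] = new_fit
        active = active[delta >= params.tol]
    fit[:, scale == 0] = 0.0
    return block - fit.T


def normalize_area(spectrum: np.ndarray) -> np.ndarray:
    """Divide a spectrum by its mean over the entire stored range."""
    spectrum = np.asarray(spectrum, dtype=float)
    finite = np.isfinite(spectrum)
    if not finite.any():
        raise NormalizationError("spectrum has no finite channels")
    mean = float(spectrum[finite].mean())
    if not np.isfinite(mean) or mean <= 0:
        raise NormalizationError(f"non-positive spectrum mean {mean}")
    return spectrum / mean


def normalize_amide2(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    band: BandDef | None = None,
) -> np.ndarray:
    """Divide a spectrum by its Amide II peak intensity."""
    if band is None:
        band = _bands.DEFAULT_BANDS["amide2"]
    intensity = _bands.band_intensity(spectrum, axis, band)
    if not np.isfinite(intensity) or intensity <= 0:
        raise NormalizationError(f"non-positive {band.name} intensity {intensity}")
    return np.asarray(spectrum, dtype=float) / intensity


def apply_plan(cube: SpectralCube, plan: PreprocessPlan) -> tuple[SpectralCube, PixelMask]:
    """Apply a plan to every pixel; returns the new cube and a validity mask.

    Pixels whose normalization is undefined (all-NaN spectrum, non-positive
    mean or Amide II intensity) are flagged False in the mask rather than
    dropped; their data is set to NaN.  The plan is echoed into the cube
    metadata.
    """
    flat = cube.flat().copy()
    n_pixels, n_channels = flat.shape
    valid = np.ones(n_pixels, dtype=bool)

    if plan.baseline is not None:
        finite = np.isfinite(flat)
        full_rows = finite.all(axis=1)
        some_rows = ~full_rows & (finite.sum(axis=1) > plan.baseline.order + 1)
        none_rows = ~full_rows & ~some_rows
        if full_rows.any():
            flat[full_rows] = _baseline_correct_block(flat[full_rows], plan.baseline)
        for idx in np.nonzero(some_rows)[0]:
            flat[idx] = baseline_correct(
                flat[idx], plan.baseline.order, plan.baseline.max_iter, plan.baseline.tol
            )
        # all-NaN / too-sparse rows pass through untouched; they will be
        # flagged invalid by any normalization step
        del none_rows

    if plan.normalization == "area":
        finite = np.isfinite(flat)
        counts = finite.sum(axis=1)
        sums = np.where(finite, flat, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts
        bad = (counts == 0) | ~np.isfinite(means) | (means <= 0)
        valid &= ~bad
        flat[~bad] /= means[~bad, None]
        flat[bad] = np.nan
    elif plan.normalization == "amide2":
        tmp = cube.with_data(flat.reshape(cube.rows, cube.cols, n_channels))
        intensities = _bands.band_intensity_map(tmp, plan.amide2_band).reshape(n_pixels)
        bad = ~np.isfinite(intensities) | (intensities <= 0)
        valid &= ~bad
        flat[~bad] /= intensities[~bad, None]
        flat[bad] = np.nan

    out = cube.with_data(
        flat.reshape(cube.rows, cube.cols, n_channels), preprocess=plan.describe()
    )
    mask = PixelMask(valid.reshape(cube.rows, cube.cols), f"preprocess[{plan.describe()}]")
    return out, mask


def six_scenarios(
    baseline: BaselineParams | None = None,
    amide2_band: BandDef | None = None,
) -> dict[str, PreprocessPlan]:
    """The six canonical plans: {raw, baseline} x {none, amide2, area}."""
    baseline = baseline or BaselineParams()
    kwargs = {} if amide2_band is None else {"amide2_band": amide2_band}
    return {
        "raw": PreprocessPlan(None, "none", **kwargs),
        "baseline": PreprocessPlan(baseline, "none", **kwargs),
        "amide2": PreprocessPlan(None, "amide2", **kwargs),
        "area": PreprocessPlan(None, "area", **kwargs),
        "baseline+amide2": PreprocessPlan(baseline, "amide2", **kwargs),
        "baseline+area": PreprocessPlan(baseline, "area", **kwargs),
    }
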