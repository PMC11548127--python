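"""Core domain types and shared numerics for hyperspectral FTIR maps.

A map is a :class:`SpectralCube`: a ``rows x cols`` grid of absorbance
spectra sharing one :class:`WavenumberAxis`.  Boolean pixel selections are
carried as :class:`PixelMask` objects, and named spectral bands as
:class:`BandDef`.  Dead pixels are represented as all-NaN spectra and are
implicitly excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FTIRMapError",
    "DomainError",
    "OutOfRangeError",
    "DegenerateMaskError",
    "DegenerateInputError",
    "NormalizationError",
    "InsufficientDataError",
    "DegenerateDistributionError",
    "WavenumberAxis",
    "SpectralCube",
    "PixelMask",
    "BandDef",
    "absorbance_from_transmittance",
    "transmittance_from_absorbance",
    "nearest_channel",
    "masked_mean_spectrum",
]


class FTIRMapError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(FTIRMapError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class OutOfRangeError(FTIRMapError, ValueError):
    """A wavenumber query falls outside the stored axis."""


class DegenerateMaskError(FTIRMapError, ValueError):
    """A mask retains too few pixels for the requested statistic."""


class DegenerateInputError(FTIRMapError, ValueError):
    """An input spectrum carries no usable (finite) data."""


class NormalizationError(FTIRMapError, ValueError):
    """A per-spectrum normalization is undefined for this spectrum."""


class InsufficientDataError(FTIRMapError, ValueError):
    """Too few finite observations for a robust statistic."""


class DegenerateDistributionError(FTIRMapError, ValueError):
    """A distribution has zero spread where spread is required."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly ascending wavenumber axis in cm^-1.

    Parameters
    ----------
    values
        Strictly increasing wavenumbers, length >= 2.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise DomainError("axis needs at least two wavenumbers")
        if not np.all(np.isfinite(values)):
            raise DomainError("axis values must be finite")
        diffs = np.diff(values)
        if not np.all(diffs > 0):
            raise DomainError("axis must be strictly ascending; flip descending input first")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_values(cls, values) -> tuple["WavenumberAxis", bool]:
        """Build an axis from possibly descending input.

        Returns the ascending axis plus a flag telling whether the input was
        flipped (callers reordering cube data must mirror the flip).
        """
        values = np.asarray(values, dtype=float)
        if values.size >= 2 and values[0] > values[-1]:
            return cls(values[::-1].copy()), True
        return cls(values), False

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Nominal channel step in cm^-1 (median of successive differences)."""
        return float(np.median(np.diff(self.values)))

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.lo <= lo and hi <= self.hi


@dataclass
class SpectralCube:
    """Absorbance cube indexed ``(row, col, channel)`` plus its axis.

    ``pixel_pitch`` is the side length of one pixel in micrometres; the
    field-of-view side is ``cols * pixel_pitch``.
    """

    data: np.ndarray
    axis: WavenumberAxis
    pixel_pitch: float = 2.7
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DomainError("cube data must be 3-D (row, col, channel)")
        if self.data.shape[2] != len(self.axis):
            raise DomainError(
                f"axis length {len(self.axis)} != channel count {self.data.shape[2]}"
            )
        if self.pixel_pitch <= 0:
            raise DomainError("pixel pitch must be positive")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def field_of_view(self) -> tuple[float, float]:
        """(height, width) of the mapped area in micrometres."""
        return (self.rows * self.pixel_pitch, self.cols * self.pixel_pitch)

    def flat(self) -> np.ndarray:
        """View of the data as ``(n_pixels, n_channels)``."""
        return self.data.reshape(self.n_pixels, self.n_channels)

    def with_data(self, data: np.ndarray, **meta: str) -> "SpectralCube":
        md = dict(self.metadata)
        md.update(meta)
        return SpectralCube(data=data, axis=self.axis, pixel_pitch=self.pixel_pitch, metadata=md)


@dataclass
class PixelMask:
    """Boolean inlier grid aligned to a cube; ``True`` marks retained pixels."""

    grid: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise DomainError("mask grid must be 2-D")

    @classmethod
    def full(cls, shape: tuple[int, int], provenance: str = "all") -> "PixelMask":
        return cls(np.ones(shape, dtype=bool), provenance)

    @property
    def retention(self) -> float:
        """Fraction of pixels retained, in [0, 1]."""
        return float(self.grid.mean())

    @property
    def n_retained(self) -> int:
        return int(self.grid.sum())

    def intersect(self, other: "PixelMask") -> "PixelMask":
        if self.grid.shape != other.grid.shape:
            raise DomainError("mask shapes differ")
        return PixelMask(self.grid & other.grid, f"({self.provenance}) & ({other.provenance})")

    def union(self, other: "PixelMask") -> "PixelMask":
        if self.grid.shape != other.grid.shape:
            raise DomainError("mask shapes differ")
        return PixelMask(self.grid | other.grid, f"({self.provenance}) | ({other.provenance})")

    def matches(self, cube: SpectralCube) -> bool:
        return self.grid.shape == (cube.rows, cube.cols)


@dataclass(frozen=True)
class BandDef:
    """Named spectral band: a centre, a peak-lookup window, and integral limits."""

    name: str
    center: float
    peak_window: float = 8.0
    integral_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        lo, hi = self.integral_range
        if lo == hi == 0.0:
            # default integral window: centre +/- 2 * peak window
            half = max(self.peak_window, 1.0) * 2.0
            object.__setattr__(self, "integral_range", (self.center - half, self.center + half))
            lo, hi = self.integral_range
        if not (lo < self.center < hi):
            raise DomainError(f"band {self.name}: need lo < center < hi, got {lo}, {self.center}, {hi}")
        if self.peak_window < 0:
            raise DomainError("peak_window must be >= 0")


def absorbance_from_transmittance(percent_t):
    """Convert percent transmittance to absorbance: ``A = 2 - log10(%T)``.

    10 %T maps to 1.0 A and 1 %T maps to 2.0 A.  Non-positive transmittance
    has no absorbance and raises :class:`DomainError`.
    """
    percent_t = np.asarray(percent_t, dtype=float)
    if np.any(percent_t <= 0):
        raise DomainError("transmittance must be positive")
    out = 2.0 - np.log10(percent_t)
    return float(out) if out.ndim == 0 else out


def transmittance_from_absorbance(absorbance):
    """Inverse of :func:`absorbance_from_transmittance`: ``%T = 10**(2 - A)``."""
    absorbance = np.asarray(absorbance, dtype=float)
    out = np.power(10.0, 2.0 - absorbance)
    return float(out) if out.ndim == 0 else out


def nearest_channel(axis: WavenumberAxis, target: float) -> int:
    """Index of the axis value closest to ``target``; ties break to the lower wavenumber."""
    if target < axis.lo - axis.spacing or target > axis.hi + axis.spacing:
        raise OutOfRangeError(
            f"target {target} cm^-1 outside axis [{axis.lo}, {axis.hi}] +/- spacing"
        )
    # argmin returns the first minimum; the axis is ascending, so ties resolve low
    return int(np.argmin(np.abs(axis.values - target)))


def masked_mean_spectrum(
    cube: SpectralCube, mask: PixelMask | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Channelwise mean and population SD over retained pixels.

    NaN channels (dead pixels) are excluded per channel.  Requires at least
    two retained pixels.
    """
    if mask is None:
        mask = PixelMask.full((cube.rows, cube.cols))
    if not mask.matches(cube):
        raise DomainError("mask shape does not match cube")
    if mask.n_retained < 2:
        raise DegenerateMaskError("need at least 2 retained pixels")
    spectra = cube.data[mask.grid]  # (n_retained, channels)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(spectra, axis=0)
        sd = np.nanstd(spectra, axis=0, ddof=0)
    return mean, sd


def cube_metadata_str(metadata: Mapping[str, str]) -> str:
    return "; ".join(f"{k}={v}" for k, v in sorted(metadata.items()))
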