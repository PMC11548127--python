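"""Seeded generator of stratum-corneum-like hyperspectral maps with ground truth.

Each pixel spectrum is built as

    thickness * (keratin_basis + lipid_weight * lipid_basis)
    + contamination * contaminant_basis + baseline_poly + noise

where ``thickness`` and ``lipid_weight`` are smooth, bounded, unit-mean
spatial fields, the per-pixel baseline is a random low-order polynomial,
hot pixels are flat +10 absorbance spikes, dead pixels are all-NaN, and
contaminant blobs are soft-edged disks carrying an extra component (ester
carbonyl at 1740 cm^-1 plus its own CH2 contribution, a sebum-like marker).

The ground-truth contaminant mask is the nominal disk (where the blob
amplitude is at least 25% of its peak); the soft tail beyond the disk edge
models sub-threshold smearing of real contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import DomainError, SpectralCube, WavenumberAxis

__all__ = [
    "SimBand",
    "SimConfig",
    "SimTruth",
    "default_sc_config",
    "simulate_map",
]

HOT_PIXEL_ABSORBANCE = 10.0
# saturated detector elements fluctuate wildly channel-to-channel; the noise
# keeps hot pixels extreme even after a polynomial baseline removes the offset
HOT_PIXEL_NOISE_SD = 1.0
# blob radial profile exp(-ln(4) (d/r)^2): amplitude 0.25 at the disk edge
_BLOB_DECAY = np.log(4.0)
# gain of the tanh squash applied to smooth fields: high gain gives the
# short-tailed, two-phase (corneocyte vs lipid matrix) distribution of real
# SC heterogeneity rather than Gaussian tails
_SQUASH_GAIN = 1.5


@dataclass(frozen=True)
class SimBand:
    """One spectral component band: centre/height/width plus line shape."""

    center: float
    height: float
    width: float
    shape: str = "gaussian"  # or "lorentzian"
    component: str = "keratin"  # keratin | lipid | contaminant


@dataclass(frozen=True)
class SimConfig:
    rows: int = 128
    cols: int = 128
    axis_lo: float = 698.0
    axis_hi: float = 3845.0
    axis_step: float = 4.0
    band_table: tuple[SimBand, ...] = ()
    thickness_cv: float = 0.20
    thickness_corr_len: int = 8
    lipid_weight_cv: float = 0.05
    baseline_order: int = 2
    baseline_scale: float = 0.05
    noise_sd: float = 0.005
    hot_frac: float = 0.005
    dead_frac: float = 0.005
    contam_frac: float = 0.015
    n_blobs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hot_frac", "dead_frac", "contam_frac"):
            value = getattr(self, name)
            if not 0 <= value < 1:
                raise DomainError(f"{name} must be in [0, 1)")
        if self.hot_frac + self.dead_frac + self.contam_frac >= 0.5:
            raise DomainError("artifact fractions must sum to < 0.5")
        if self.thickness_cv < 0 or self.lipid_weight_cv < 0:
            raise DomainError("coefficients of variation must be >= 0")
        if self.axis_step <= 0:
            raise DomainError("axis step must be positive")
        if self.rows < 1 or self.cols < 1:
            raise DomainError("grid must have at least one pixel")

    def make_axis(self) -> WavenumberAxis:
        n = int(np.floor((self.axis_hi - self.axis_lo) / self.axis_step)) + 1
        return WavenumberAxis(self.axis_lo + self.axis_step * np.arange(n))


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cube."""

    artifact_mask: np.ndarray  # hot or dead pixels
    contam_mask: np.ndarray  # nominal contaminant disks
    thickness_field: np.ndarray
    config_echo: SimConfig
    hot_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    dead_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    contam_amplitude: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def outlier_mask(self) -> np.ndarray:
        """Union of every injected defect (hot, dead, contaminant disks)."""
        return self.artifact_mask | self.contam_mask


def default_sc_config(seed: int = 0) -> SimConfig:
    """Default SC-like configuration: 128x128, 698-3845 cm^-1 at 4 cm^-1 step."""
    bands = (
        SimBand(1548.0, 0.55, 22.0, "gaussian", "keratin"),  # Amide II
        SimBand(1652.0, 0.75, 25.0, "gaussian", "keratin"),  # Amide I
        SimBand(2850.0, 0.20, 15.0, "gaussian", "lipid"),  # CH2 symmetric
        SimBand(2920.0, 0.30, 16.0, "gaussian", "lipid"),  # CH2 asymmetric
        SimBand(1740.0, 0.50, 15.0, "gaussian", "contaminant"),  # ester carbonyl
        SimBand(2920.0, 0.45, 16.0, "gaussian", "contaminant"),
        SimBand(2850.0, 0.30, 15.0, "gaussian", "contaminant"),
    )
    return SimConfig(band_table=bands, seed=seed)


def _line(shape: str, axis: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    if shape == "gaussian":
        return height * np.exp(-0.5 * ((axis - center) / width) ** 2)
    if shape == "lorentzian":
        return height * width**2 / ((axis - center) ** 2 + width**2)
    raise DomainError(f"unknown line shape {shape!r}")


def component_basis(config: SimConfig, component: str) -> np.ndarray:
    axis = config.make_axis().values
    basis = np.zeros_like(axis)
    for band in config.band_table:
        if band.component == component:
            basis += _line(band.shape, axis, band.center, band.height, band.width)
    return basis


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], corr_len: int, cv: float) -> np.ndarray:
    """Unit-mean bounded smooth field with the requested coefficient of variation.

    Moving-average-smoothed white noise squashed through tanh: bounded support
    (multiplier stays positive for cv <= 0.25) and smooth over ~corr_len px.
    """
    if cv == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.uniform_filter(white, size=max(1, corr_len), mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.ones(shape)
    z = (smooth - smooth.mean()) / sd
    squashed = np.tanh(_SQUASH_GAIN * z)
    squashed -= squashed.mean()
    ssd = squashed.std()
    if ssd == 0:
        return np.ones(shape)
    return 1.0 + cv * squashed / ssd


def _place_blobs(
    rng: np.random.Generator, shape: tuple[int, int], contam_frac: float, n_blobs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-edged disks; returns (amplitude field in [0,1], nominal disk mask)."""
    rows, cols = shape
    amplitude = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    n_pixels = rows * cols
    target = int(round(contam_frac * n_pixels))
    if target == 0:
        return amplitude, mask
    rr, cc = np.mgrid[0:rows, 0:cols]
    # typical radius sized so ~n_blobs disks cover the target fraction
    r_typ = float(np.clip(np.sqrt(target / (np.pi * max(1, n_blobs))), 2.0, 6.0))
    for _ in range(200):
        remaining = target - int(mask.sum())
        if remaining <= 0:
            break
        radius = float(rng.uniform(0.7, 1.3)) * r_typ
        # shrink late blobs so the final fraction lands near the target
        radius = min(radius, max(1.5, float(np.sqrt(remaining / np.pi)) + 0.5))
        r0 = rng.uniform(0, rows - 1)
        c0 = rng.uniform(0, cols - 1)
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        amplitude = np.maximum(amplitude, np.exp(-_BLOB_DECAY * d2 / radius**2))
        mask |= d2 <= radius**2
    return amplitude, mask


def simulate_map(config: SimConfig) -> tuple[SpectralCube, SimTruth]:
    """Generate one seeded SC-like cube plus its ground truth.

    Identical configs (including seed) produce bit-identical output.
    """
    axis = config.make_axis()
    for band in config.band_table:
        if not (axis.lo <= band.center <= axis.hi):
            raise DomainError(f"band at {band.center} cm^-1 outside the simulated axis")

    rng = np.random.default_rng(config.seed)
    shape = (config.rows, config.cols)
    n_pixels = config.rows * config.cols

    keratin = component_basis(config, "keratin")
    lipid = component_basis(config, "lipid")
    contaminant = component_basis(config, "contaminant")

    thickness = _smooth_unit_field(rng, shape, config.thickness_corr_len, config.thickness_cv)
    lipid_weight = _smooth_unit_field(rng, shape, config.thickness_corr_len, config.lipid_weight_cv)

    data = (
        thickness[..., None] * (keratin[None, None, :] + lipid_weight[..., None] * lipid[None, None, :])
    )

    contam_amp, contam_mask = _place_blobs(rng, shape, config.contam_frac, config.n_blobs)
    if contam_amp.any():
        data = data + contam_amp[..., None] * contaminant[None, None, :]

    if config.baseline_scale > 0 and config.baseline_order >= 0:
        x = np.linspace(-1.0, 1.0, len(axis))
        powers = np.vander(x, config.baseline_order + 1, increasing=True)  # (N, order+1)
        coeffs = rng.uniform(
            -config.baseline_scale, config.baseline_scale, size=shape + (config.baseline_order + 1,)
        )
        # scattering-like drift: offsets vary strongly pixel-to-pixel with a
        # positive bias, so raw band intensities sit above corrected ones
        coeffs[..., 0] = rng.uniform(
            -config.baseline_scale, 3.0 * config.baseline_scale, size=shape
        )
        data = data + coeffs @ powers.T

    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)

    hot_mask = np.zeros(shape, dtype=bool)
    dead_mask = np.zeros(shape, dtype=bool)
    n_hot = int(round(config.hot_frac * n_pixels))
    n_dead = int(round(config.dead_frac * n_pixels))
    if n_hot + n_dead > 0:
        chosen = rng.choice(n_pixels, size=n_hot + n_dead, replace=False)
        hot_flat = np.zeros(n_pixels, dtype=bool)
        dead_flat = np.zeros(n_pixels, dtype=bool)
        hot_flat[chosen[:n_hot]] = True
        dead_flat[chosen[n_hot:]] = True
        hot_mask = hot_flat.reshape(shape)
        dead_mask = dead_flat.reshape(shape)
        data[hot_mask] += HOT_PIXEL_ABSORBANCE + rng.normal(
            0.0, HOT_PIXEL_NOISE_SD, size=(n_hot, len(axis))
        )
        data[dead_mask] = np.nan

    cube = SpectralCube(
        data=data,
        axis=axis,
        pixel_pitch=2.7,
        metadata={"source": "simulate", "seed": str(config.seed)},
    )
    truth = SimTruth(
        artifact_mask=hot_mask | dead_mask,
        contam_mask=contam_mask,
        thickness_field=thickness,
        config_echo=config,
        hot_mask=hot_mask,
        dead_mask=dead_mask,
        contam_amplitude=contam_amp,
    )
    return cube, truth


def simulate_batch(config: SimConfig, seeds: Sequence[int]) -> list[tuple[SpectralCube, SimTruth]]:
    """Convenience: one map per seed, sharing every other parameter."""
    return [simulate_map(replace(config, seed=int(s))) for s in seeds]
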