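"""Two outlier-removal protocols: histogram/Tukey-fence and PCA score-distance.

The histogram route thresholds per-band intensity distributions with Tukey
fences ``[Q1 - k*IQR, Q3 + k*IQR]`` (linear-interpolation quantiles) and
combines per-band outlier sets by union or intersection.  The PCA route
standardizes channels, projects onto the leading components, and flags
pixels whose Euclidean distance from the componentwise median score exceeds
``threshold_c`` times the median distance.  Dead (all-NaN) pixels are
automatic outliers in both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import bands as _bands
from .core import (
    BandDef,
    DegenerateDistributionError,
    InsufficientDataError,
    PixelMask,
    SpectralCube,
)

__all__ = [
    "FenceParams",
    "PcaParams",
    "tukey_fences",
    "fd_bin_width",
    "fd_bin_width_from_iqr",
    "band_histogram",
    "histogram_outliers",
    "pca_outliers",
    "DEFAULT_K_GRID",
    "DEFAULT_THRESHOLD_GRID",
]

logger = logging.getLogger(__name__)

# k = 1.5 flags "outliers", k = 3 "far out"; 1.0 and 0.5 are the stricter probes
DEFAULT_K_GRID = (0.5, 1.0, 1.5, 3.0)
DEFAULT_THRESHOLD_GRID = (2.0, 3.0, 4.0)

_DEFAULT_FENCE_BANDS = ("amide2", "amide1", "ch2_asym")


def _default_fence_bands() -> tuple[BandDef, ...]:
    return tuple(_bands.DEFAULT_BANDS[name] for name in _DEFAULT_FENCE_BANDS)


@dataclass(frozen=True)
class FenceParams:
    k: float = 1.5
    bands: tuple[BandDef, ...] = field(default_factory=_default_fence_bands)
    combine: str = "union"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("fence multiplier k must be >= 0")
        if len(self.bands) < 1:
            raise ValueError("at least one band is required")
        if self.combine not in ("union", "intersection"):
            raise ValueError("combine must be 'union' or 'intersection'")


@dataclass(frozen=True)
class PcaParams:
    n_components: int = 2
    threshold_c: float = 3.0
    scale_channels: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.threshold_c <= 0:
            raise ValueError("threshold_c must be positive")


def tukey_fences(values: np.ndarray, k: float) -> tuple[float, float]:
    """Tukey fences ``(Q1 - k*IQR, Q3 + k*IQR)``; bounds are inclusive for inliers."""
    values = np.asarray(values, dtype=float).ravel()
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise InsufficientDataError(f"need >= 4 finite values, got {finite.size}")
    q1, q3 = np.percentile(finite, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def fd_bin_width_from_iqr(iqr: float, n: int) -> float:
    """Freedman-Diaconis width ``2 * IQR * n**(-1/3)``."""
    if n < 1:
        raise InsufficientDataError("n must be >= 1")
    if iqr <= 0:
        raise DegenerateDistributionError("zero IQR: fall back to a single bin")
    return 2.0 * iqr * n ** (-1.0 / 3.0)


def fd_bin_width(values: np.ndarray) -> float:
    """Freedman-Diaconis bin width of the finite observations in ``values``."""
    values = np.asarray(values, dtype=float).ravel()
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise InsufficientDataError(f"need >= 4 finite values, got {finite.size}")
    q1, q3 = np.percentile(finite, [25.0, 75.0])
    return fd_bin_width_from_iqr(float(q3 - q1), finite.size)


def band_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with Freedman-Diaconis bin width (single bin when IQR = 0)."""
    values = np.asarray(values, dtype=float).ravel()
    finite = values[np.isfinite(values)]
    try:
        width = fd_bin_width(finite)
        n_bins = max(1, int(np.ceil(np.ptp(finite) / width)))
    except DegenerateDistributionError:
        n_bins = 1
    return np.histogram(finite, bins=n_bins)


def histogram_outliers(
    cube: SpectralCube,
    params: FenceParams,
    band_maps: dict[str, np.ndarray] | None = None,
) -> PixelMask:
    """Fence-threshold per-band intensity maps and combine the outlier sets.

    ``band_maps`` may carry precomputed intensity grids (keyed by band name);
    missing ones are computed from the cube.  NaN pixels are always outliers.
    Bands whose distribution is degenerate (zero IQR) flag nothing and emit a
    warning.
    """
    shape = (cube.rows, cube.cols)
    if params.combine == "union":
        outlier = np.zeros(shape, dtype=bool)
    else:
        outlier = np.ones(shape, dtype=bool)
    degenerate: list[str] = []
    invalid = np.zeros(shape, dtype=bool)
    for band in params.bands:
        if band_maps is not None and band.name in band_maps:
            values = np.asarray(band_maps[band.name], dtype=float)
        else:
            values = _bands.band_intensity_map(cube, band)
        invalid |= ~np.isfinite(values)
        finite = values[np.isfinite(values)]
        if finite.size < 4 or np.percentile(finite, 75) == np.percentile(finite, 25):
            degenerate.append(band.name)
            band_out = np.zeros(shape, dtype=bool)
        else:
            lo, hi = tukey_fences(finite, params.k)
            band_out = (values < lo) | (values > hi)
        if params.combine == "union":
            outlier |= band_out
        else:
            outlier &= band_out
    if degenerate:
        warnings.warn(
            f"degenerate intensity distribution for bands {degenerate}; no fence applied",
            RuntimeWarning,
            stacklevel=2,
        )
    # dead / invalid pixels are auto-outliers regardless of combine mode
    outlier |= invalid
    provenance = (
        f"histogram[k={params.k},bands={','.join(b.name for b in params.bands)},combine={params.combine}]"
    )
    return PixelMask(~outlier, provenance)


def pca_outliers(
    cube: SpectralCube, params: PcaParams
) -> tuple[PixelMask, pd.DataFrame]:
    """PCA score-distance outlier detection.

    Channels are standardized (zero mean, unit variance) when
    ``scale_channels`` is set; zero-variance channels are dropped with a log
    notice.  A pixel is an outlier iff its Euclidean distance from the
    componentwise median score exceeds ``threshold_c`` times the median
    distance.  Pixels with any non-finite channel are automatic outliers.
    """
    flat = cube.flat()
    valid = np.isfinite(flat).all(axis=1)
    n_valid = int(valid.sum())
    if n_valid < params.n_components + 1:
        raise InsufficientDataError(
            f"need >= n_components+1={params.n_components + 1} valid pixels, got {n_valid}"
        )
    x = flat[valid]

    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if params.scale_channels:
        if not keep.all():
            logger.info("dropping %d zero-variance channels before PCA", int((~keep).sum()))
        x = x[:, keep]
        sd = sd[keep]
        x = (x - x.mean(axis=0)) / sd

    n_components = min(params.n_components, x.shape[1], x.shape[0] - 1) if x.shape[1] else 0
    if n_components == 0:
        # every channel constant: all pixels coincide, nothing is an outlier
        scores = np.zeros((n_valid, params.n_components))
    else:
        pca = PCA(n_components=n_components, svd_solver="covariance_eigh", random_state=0)
        scores = pca.fit_transform(x)
        if n_components < params.n_components:
            scores = np.pad(scores, ((0, 0), (0, params.n_components - n_components)))

    med = np.median(scores, axis=0)
    dist = np.sqrt(((scores - med) ** 2).sum(axis=1))
    med_dist = float(np.median(dist))
    # numerical floor so coincident clouds (distances ~ machine epsilon) stay inliers
    floor = 1e-9 * (1.0 + float(np.abs(scores).max(initial=0.0)))
    threshold = max(params.threshold_c * med_dist, floor)
    out_valid = dist > threshold

    outlier_flat = ~valid  # non-finite pixels are auto-outliers
    idx = np.nonzero(valid)[0]
    outlier_flat[idx[out_valid]] = True

    rows, cols = np.divmod(idx, cube.cols)
    table = pd.DataFrame({"row": rows, "col": cols})
    for j in range(scores.shape[1]):
        table[f"pc{j + 1}"] = scores[:, j]
    table["distance"] = dist
    table["outlier"] = out_valid

    provenance = (
        f"pca[n_components={params.n_components},threshold_c={params.threshold_c},"
        f"scale_channels={params.scale_channels}]"
    )
    mask = PixelMask(~outlier_flat.reshape(cube.rows, cube.cols), provenance)
    return mask, table
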