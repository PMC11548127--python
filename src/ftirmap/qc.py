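"""Dispersion, retention, and compactness metrics plus method comparison.

The per-band dispersion metric is the normalized SD (population SD divided
by the mean, i.e. the coefficient of variation).  "Compactness" of an
inlier mask is the share of inlier pixels belonging to the largest
4-connected component.  :func:`compare_methods` crosses preprocessing plans
with outlier filters on one map and emits a tidy long-format table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import bands as _bands
from . import outliers as _outliers
from . import preprocess as _preprocess
from .core import (
    BandDef,
    DegenerateMaskError,
    DomainError,
    PixelMask,
    SpectralCube,
    masked_mean_spectrum,
)

__all__ = [
    "QCReport",
    "normalized_sd",
    "compactness",
    "band_stats",
    "confusion_rates",
    "apply_filter",
    "compare_methods",
    "write_report",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)

DEFAULT_QC_BANDS = ("amide2", "amide1", "ch2_sym", "ch2_asym")


def normalized_sd(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Population SD divided by the mean over retained finite values (CV)."""
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise DegenerateMaskError("need >= 2 retained finite values")
    mean = values.mean()
    if mean == 0:
        raise DomainError("zero mean: CV undefined")
    return float(values.std(ddof=0) / mean)


def compactness(mask: PixelMask) -> float:
    """Largest 4-connected inlier component as a fraction of all inliers."""
    n_inliers = mask.n_retained
    if n_inliers == 0:
        raise DegenerateMaskError("mask has no inlier pixels")
    labels, n_components = ndimage.label(mask.grid, structure=_FOUR_CONN)
    if n_components == 0:
        raise DegenerateMaskError("mask has no inlier pixels")
    largest = np.bincount(labels.ravel())[1:].max()
    return float(largest / n_inliers)


def band_stats(
    cube: SpectralCube,
    band: BandDef,
    mask: PixelMask | None = None,
) -> tuple[float, float, float]:
    """(mean, population SD, CV) of a band's intensity over retained pixels."""
    values = _bands.band_intensity_map(cube, band)
    grid = None if mask is None else mask.grid
    if grid is not None:
        values = values[grid]
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise DegenerateMaskError("need >= 2 retained finite pixels")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    cv = sd / mean if mean != 0 else float("nan")
    return mean, sd, cv


def confusion_rates(mask: PixelMask, truth_outliers: np.ndarray) -> tuple[float, float]:
    """(sensitivity, specificity) of a mask against a ground-truth outlier grid.

    Sensitivity: fraction of true outlier pixels flagged (mask False).
    Specificity: fraction of clean pixels retained (mask True).
    """
    truth = np.asarray(truth_outliers, dtype=bool)
    if truth.shape != mask.grid.shape:
        raise DomainError("truth shape does not match mask")
    flagged = ~mask.grid
    n_out = int(truth.sum())
    n_clean = truth.size - n_out
    sensitivity = float(flagged[truth].sum() / n_out) if n_out else float("nan")
    specificity = float((~flagged[~truth]).sum() / n_clean) if n_clean else float("nan")
    return sensitivity, specificity


@dataclass
class QCReport:
    """Per-map quality summary for one plan/filter combination."""

    map_id: str
    plan: str
    filter: str
    mean_spectrum: np.ndarray
    sd_spectrum: np.ndarray
    band_table: pd.DataFrame  # columns: band, mean, sd, cv
    ratios: dict[str, float]
    retention: float
    compactness: float
    provenance: str = ""
    artifacts: dict[str, str] = field(default_factory=dict)


def apply_filter(
    cube: SpectralCube,
    params: "_outliers.FenceParams | _outliers.PcaParams | None",
) -> PixelMask:
    """Dispatch a filter parameter object to its protocol; None = keep all."""
    if params is None:
        return PixelMask.full((cube.rows, cube.cols), "none")
    if isinstance(params, _outliers.FenceParams):
        return _outliers.histogram_outliers(cube, params)
    if isinstance(params, _outliers.PcaParams):
        mask, _ = _outliers.pca_outliers(cube, params)
        return mask
    raise DomainError(f"unknown filter parameter type {type(params)!r}")


def compare_methods(
    cube: SpectralCube,
    plans: dict[str, "_preprocess.PreprocessPlan"],
    filters: dict[str, "_outliers.FenceParams | _outliers.PcaParams | None"],
    qc_bands: dict[str, BandDef] | None = None,
    map_id: str = "map",
) -> pd.DataFrame:
    """Cross plans x filters on one map; long-format table, canonical order.

    Per-cell failures are recorded in the ``error`` column instead of
    aborting the grid.  Retention always equals the combined mask's true
    fraction.
    """
    if not plans or not filters:
        raise DomainError("need at least one plan and one filter")
    if qc_bands is None:
        qc_bands = {name: _bands.DEFAULT_BANDS[name] for name in DEFAULT_QC_BANDS}

    rows = []
    for plan_name in sorted(plans):
        plan = plans[plan_name]
        try:
            processed, valid = _preprocess.apply_plan(cube, plan)
        except Exception as exc:  # pragma: no cover - defensive
            for filter_name in sorted(filters):
                for band_name in qc_bands:
                    rows.append(_row(map_id, plan_name, filter_name, band_name, error=type(exc).__name__))
            continue
        for filter_name in sorted(filters):
            try:
                mask = apply_filter(processed, filters[filter_name]).intersect(valid)
                comp = compactness(mask)
            except Exception as exc:
                for band_name in qc_bands:
                    rows.append(_row(map_id, plan_name, filter_name, band_name, error=type(exc).__name__))
                continue
            for band_name, band in qc_bands.items():
                try:
                    mean, sd, cv = band_stats(processed, band, mask)
                    rows.append(
                        _row(
                            map_id, plan_name, filter_name, band_name,
                            mean=mean, sd=sd, cv=cv,
                            retention=mask.retention, compactness=comp,
                        )
                    )
                except Exception as exc:
                    rows.append(_row(map_id, plan_name, filter_name, band_name, error=type(exc).__name__))

    table = pd.DataFrame(rows)
    return table.sort_values(
        ["map_id", "plan", "filter", "band"], kind="mergesort", ignore_index=True
    )


def _row(map_id, plan, filter_name, band, mean=np.nan, sd=np.nan, cv=np.nan,
         retention=np.nan, compactness=np.nan, error=""):
    return {
        "map_id": map_id,
        "plan": plan,
        "filter": filter_name,
        "band": band,
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "retention": retention,
        "compactness": compactness,
        "error": error,
    }


def write_report(
    cube: SpectralCube,
    mask: PixelMask,
    qc_bands: dict[str, BandDef],
    outdir,
    map_id: str = "map",
) -> QCReport:
    """Emit report.csv, mean_spectrum.csv and mask_overlay.png for one map."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mean, sd = masked_mean_spectrum(cube, mask)
    _io.write_spectrum_csv(outdir / "mean_spectrum.csv", cube.axis, mean, sd)

    records = []
    for name, band in qc_bands.items():
        b_mean, b_sd, b_cv = band_stats(cube, band, mask)
        records.append({"band": name, "mean": b_mean, "sd": b_sd, "cv": b_cv})
    band_table = pd.DataFrame(records)

    ratios = {}
    for num, den, label in (("amide1", "amide2", "1652/1548"), ("ch2_asym", "ch2_sym", "2920/2850")):
        if num in qc_bands and den in qc_bands:
            num_mean = band_table.loc[band_table["band"] == num, "mean"].iloc[0]
            den_mean = band_table.loc[band_table["band"] == den, "mean"].iloc[0]
            ratios[label] = float(num_mean / den_mean) if den_mean else float("nan")

    comp = compactness(mask)
    long = band_table.assign(
        map_id=map_id, plan=cube.metadata.get("preprocess", "unknown"),
        filter=mask.provenance, retention=mask.retention, compactness=comp, error="",
    )[["map_id", "plan", "filter", "band", "mean", "sd", "cv", "retention", "compactness", "error"]]
    long.to_csv(outdir / "report.csv", index=False)

    _plot_overlay(cube, mask, qc_bands, outdir / "mask_overlay.png")

    return QCReport(
        map_id=map_id,
        plan=cube.metadata.get("preprocess", "unknown"),
        filter=mask.provenance,
        mean_spectrum=mean,
        sd_spectrum=sd,
        band_table=band_table,
        ratios=ratios,
        retention=mask.retention,
        compactness=comp,
        provenance=mask.provenance,
        artifacts={
            "report": str(outdir / "report.csv"),
            "mean_spectrum": str(outdir / "mean_spectrum.csv"),
            "mask_overlay": str(outdir / "mask_overlay.png"),
        },
    )


def _plot_overlay(cube, mask, qc_bands, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    band = next(iter(qc_bands.values()))
    grid = _bands.band_intensity_map(cube, band)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(grid, cmap="viridis", interpolation="nearest")
    overlay = np.zeros(mask.grid.shape + (4,))
    overlay[~mask.grid] = (1.0, 0.0, 0.0, 0.8)  # outliers in red
    ax.imshow(overlay, interpolation="nearest")
    ax.set_title(f"{band.name} intensity, outliers flagged")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
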