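# ftirmap

Processing pipeline for hyperspectral FTIR absorbance maps of thin
biological sections (stratum-corneum-like samples): baseline correction,
spectrum normalization, band chemometrics, two outlier-removal protocols,
and the QC metrics needed to compare them — together with a seeded
synthetic-map generator that provides ground truth for every defect it
injects.

## What is in the box

| module | purpose |
| --- | --- |
| `ftirmap.core` | domain types (`SpectralCube`, `WavenumberAxis`, `PixelMask`, `BandDef`), absorbance/transmittance conversion, masked statistics |
| `ftirmap.io` | HDF5 cube container, CSV spectrum/grid exports, mask PNG+CSV |
| `ftirmap.simulate` | seeded SC-like map generator: smooth thickness / lipid fields, per-pixel polynomial drift, noise, hot/dead pixels, soft-edged contaminant blobs, full ground truth |
| `ftirmap.preprocess` | iterative (clip-above-fit) polynomial baseline correction; area and Amide II normalization; the six canonical plans |
| `ftirmap.bands` | band intensities (windowed peak maximum), trapezoidal integrals, ratios, chemical maps |
| `ftirmap.outliers` | Tukey-fence histogram thresholding (Freedman–Diaconis bin widths) and PCA score-distance detection |
| `ftirmap.qc` | normalized SD (CV), retention, 4-connected compactness, plan × filter comparison tables, report writer |

## CLI

```bash
# 1. generate a synthetic map (defaults: 128x128 pixels, 698-3845 cm^-1 at 4 cm^-1)
ftirmap simulate --seed 42 --out map.h5 --truth truth.h5

# 2. baseline-correct and area-normalize every spectrum
ftirmap preprocess --in map.h5 --baseline poly:2 --norm area --out map_pp.h5

# 3a. flag outliers with Tukey fences on three band-intensity histograms
ftirmap filter --in map_pp.h5 --method histogram --k 1.5 \
    --bands amide2,amide1,ch2_asym --combine union --out mask

# 3b. ... or with PCA score distance
ftirmap filter --in map_pp.h5 --method pca --components 2 --threshold 3 --out mask

# 4. per-map QC report (report.csv, mean_spectrum.csv, mask_overlay.png)
ftirmap report --in map_pp.h5 --mask mask.csv --out report/
```

`simulate --config cfg.json` accepts a flat JSON mirror of `SimConfig`
(any subset of fields; `band_table` as a list of
`{center, height, width, shape, component}` objects).

## Python API sketch

```python
import ftirmap as fm

cube, truth = fm.simulate_map(fm.default_sc_config(seed=1))
plan = fm.PreprocessPlan(fm.BaselineParams(order=2), "area")
processed, valid = fm.apply_plan(cube, plan)

fences = fm.FenceParams(k=1.5)                  # union over amide2/amide1/ch2_asym
mask = fm.histogram_outliers(processed, fences)
pca_mask, scores = fm.pca_outliers(processed, fm.PcaParams(n_components=2, threshold_c=3))

table = fm.compare_methods(cube, fm.six_scenarios(), {"fence": fences, "none": None})
```

## Conventions

* Absorbance cubes are indexed `(row, col, channel)`, row 0 at the top;
  wavenumber axes are stored ascending (descending input is flipped on read
  and recorded in metadata).
* Dead pixels are all-NaN spectra and are excluded from every statistic;
  they are automatic outliers in both detection protocols.
* All standard deviations are population SDs; normalized SD = SD / mean.
* Negative absorbance after baseline subtraction is not clipped.
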