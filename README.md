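# divdrought

Does forest plant diversity make forests more resistant to drought?
`divdrought` is a tested re-implementation of a satellite-style analysis
pipeline that asks this question with raster data alone — no plot-level
surveys required — and a synthetic-scene generator that makes every stage
of the analysis verifiable against known ground truth.

It is aimed at ecologists and remote-sensing scientists who want to run,
scrutinize, or extend this kind of analysis: every stage is an importable,
unit-tested function, and the whole chain runs end-to-end on generated
data in seconds.

## The analysis

Three maps are built and then related to each other:

1. **Plant diversity** via the spectral variation hypothesis.  For each
   forest pixel of a multiband reflectance image, the coefficient of
   variation of each band over a 7×7 neighborhood is averaged over the
   Δ = 10 bands:

   CV = (1/Δ) Σ_λ std(ρ_λ) / mean(ρ_λ)

   Higher neighborhood spectral variability ⇒ more distinct canopies ⇒
   higher plant diversity.  Multi-date CV maps are averaged and
   block-mean aggregated to the 1-km analysis grid.

2. **Drought sensitivity** γ.  Monthly NDVI/EVI series are standardized
   per calendar month into anomalies, SVI_{i,j} = (VI_{i,j} − μ_i)/σ_i,
   and correlated (Pearson) against the standardized
   precipitation-evapotranspiration index (SPEI) at 1/3/6-month
   timescales, pooling the dry-season months (Jan–Apr, Nov, Dec) over
   2000–2018 (n up to 114 pairs/pixel).  γ near +1 means the canopy
   tracks water availability (drought-sensitive, low resistance); γ ≤ 0
   means drought-resistant.

3. **Climate dryness.**  Aridity index AI = mean over years of annual
   P/PET (mean of ratios), classified Hyper-arid < 0.05 ≤ Arid < 0.2 ≤
   Semi-arid < 0.5 ≤ Dry subhumid < 0.65 ≤ Humid; plus drought frequency,
   the fraction of months with 12-month SPEI < −0.5.

The headline statistic comes from a **non-overlapping moving-window
analysis**: in each 50×50-pixel block (30/40/60 as robustness checks),
the Pearson correlation r between the diversity map and the γ map is
computed along with block-mean AI and drought frequency.  r < 0 in a
block means higher diversity goes with lower drought sensitivity — a
diversity benefit.  Regressing block r on block dryness shows where the
benefit is strongest.

The synthetic generator plants all of this structure — a smooth latent
diversity field driving local spectral heterogeneity, AR(1) drought
indices, VI series coupled to SPEI with a sensitivity that decreases
with diversity more steeply in drier climates — so the pipeline's output
can be checked against the planted truth.

## Worked example

```python
from divdrought import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))  # 120x120 km synthetic domain
```

Inspecting the report (see `tests/test_pipeline.py` for the schema):

```text
dry-season positive area (SPEI_1): 99.8%
wet-month positive area (July, SPEI_1): 57.7%
negative block proportion (50 px windows): 100.0%
r vs aridity index:    slope = +1.061, spearman rho = +0.80
r vs drought frequency: slope = -6.147, spearman rho = -0.80
zonal richness vs tau_CV: r = 0.90 (p = 2.4e-06, 16 zones)
drought years: 2007, 2009, 2013, 2015, 2017, 2018
```

Read this as: nearly all forest pixels are drought-sensitive in the dry
season but only ~58% in the wet months (the planted seasonal-coupling
contrast); every 50-px window shows a negative diversity–sensitivity
correlation (a diversity benefit everywhere); the benefit weakens as the
climate gets wetter (positive slope on AI) and strengthens where drought
is frequent (negative slope on drought frequency); and zonal CV sums
track the planted species richness of the pseudo-counties.

The same stages are available as shell commands (`divdrought simulate`,
`diversity`, `svi`, `sensitivity`, `climate`, `droughtfreq`, `windows`,
`trend`, `zonal`, `run`) over TIFF/NetCDF/CSV files; `divdrought run
--seed 1 --out report.json` reproduces the report above.

## Layout

| module | role |
| --- | --- |
| `raster_grid` | grids, masked rasters, nearest-neighbor resampling, block tiling |
| `spectral_diversity` | windowed-CV diversity index, multi-scene averaging, aggregation |
| `vegetation_indices` | monthly max-value compositing, NDVI/EVI, SVI standardization |
| `drought_metrics` | SPEI stacks, aridity index + climate classes, drought frequency |
| `sensitivity` | pixelwise γ maps (monthly and pooled dry season), area proportions |
| `window_analysis` | non-overlapping block correlations, dryness trend summaries |
| `zonal_validation` | county-style zonal CV statistics vs richness tables |
| `synthetic_data` | ground-truthed generator for every pipeline input |
| `pipeline`, `cli` | end-to-end orchestration and the `divdrought` command |

`docs/methods.md` documents the model assumptions, parameter defaults,
and the generator's design in detail.
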