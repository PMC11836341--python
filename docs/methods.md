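# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## 1. Diversity from spectral variation

The diversity index is the band-averaged windowed coefficient of
variation of surface reflectance.  For forest pixel *(i, j)* and window
*W* (side `window_size`, default 7, clipped at image edges and restricted
to valid forest pixels):

    CV(i, j) = (1/Δ) Σ_λ  std_W(ρ_λ) / mean_W(ρ_λ)

Choices:

* **Sample standard deviation** (divisor n−1) by default, matching common
  spectral-diversity practice; `ddof=0` switches to the population
  convention.  The two differ by a factor √((n−1)/n) and do not change
  ranks, so downstream rank-based results are unaffected.
* **Support guard**: windows with fewer than `min_valid` (default 10)
  contributing pixels are invalid — a 7×7 window nominally has 49, but
  forest masking and edge clipping can cut deep.
* **Zero-mean bands invalidate the window** rather than being skipped:
  reflectance that is exactly zero across a window signals bad data, not
  a dark surface.
* **Multi-date handling**: the CV is computed per scene and the CV maps
  averaged cellwise (mask-aware), not computed on a temporally averaged
  scene; temporal averaging first would suppress precisely the spatial
  variance the index measures.
* **Aggregation to the analysis grid** (1 km) is the block mean of valid
  fine cells.  CV is a neighborhood statistic, so averaging is the
  natural fine-to-coarse reducer; nearest-neighbor resampling is also
  available and is what the climate grids use.

Numerics: windowed sums use padded summed-area tables; the variance pass
runs on band values centered on their global mean, which removes the
catastrophic cancellation that otherwise leaves ~1e−8 residue on
constant windows.  Equivalence with a brute-force per-pixel loop is
tested to 1e−10.

## 2. Vegetation anomalies (SVI)

Monthly vegetation indices come from maximum-value compositing of
clear-sky reflectance within each month (per band, then NDVI/EVI from
the composited bands — not max-VI compositing, which differs).  Quality
flags are modeled as a per-date boolean `clear` layer; decoding any
specific sensor's QC bitfields is out of scope, and a thin adapter can
populate the flag from real products.

Standardization is per pixel and calendar month across years:
SVI = (VI − μ_i)/σ_i with the sample convention for σ_i.  Pixels need
`min_years` (default 10 of 19) valid years per month, and months with
zero variance are invalid.  Standardization is exactly invariant to
positive affine transforms of a month's series, so SVI inherits no
sensor calibration scale.

## 3. Drought metrics

SPEI grids are consumed as data, exactly as an analysis of real archives
would consume a published SPEI product; the log-logistic fitting of a
water balance is deliberately not re-implemented.  Conventions:

* drought month: SPEI_12 < −0.5 (strict); exceptional drought < −2.0;
* drought frequency: drought months / months with valid SPEI;
* year labels: region-mean December SPEI_12, with the wet cutoff (+0.5)
  chosen symmetric to the drought cutoff;
* aridity index: mean over years of annual P/PET — the mean of ratios,
  not the ratio of means (they differ; the former weights years
  equally);
* climate classes: left-closed intervals at 0.05 / 0.2 / 0.5 / 0.65.

For synthetic data, longer timescales are built as k-month trailing
means of the monthly proxy, re-standardized per calendar month.

## 4. Drought sensitivity γ

γ is the Pearson correlation of a pixel's SVI and SPEI series.  The
dry-season γ pools all (year, month) pairs with month ∈ {1, 2, 3, 4, 11,
12} into one correlation of up to 114 pairs (the correlation is defined
over one sample, and pooling is what gives it statistical teeth); a
per-month-average variant exists behind a flag for comparison.  Monthly
maps correlate across years (n ≤ 19) with `min_samples` 10; pooled maps
use 30.  No lead/lag is applied between SVI and SPEI.  Two-sided
p-values from the t transform are recorded but **not** used to mask
pixels before area proportions are computed; a significance mask is
available as an option.  Series that are constant over their valid slots
have no defined correlation and are invalidated (detected by exact
min/max equality, not by a variance epsilon).

Estimator behavior (verified by simulation): bias → 0 with n, spread
≈ (1 − s²)/√n at planted coupling s, i.e. ~0.09 at n = 114 and ~0.15 per
month at n = 19.  This estimation noise is what attenuates block-level
correlations below the truth-field values.

## 5. Moving-window analysis

The map is partitioned into non-overlapping blocks (no sliding overlap,
so every block is statistically independent territory).  Per block:
Pearson r of (diversity, γ) over jointly valid pixels, plus block means
of each covariate over the same pixels (forest pixels only).  Blocks
with fewer than `min_pixels` (default 30) valid pixels or zero variance
are dropped, and **partial edge tiles are excluded by default** —
unequal support would bias their correlations.  The trend stage fits OLS
of r on the covariate and a Spearman rank correlation, and reports the
fraction of negative-r blocks.

With the default 120×120 domain, a 50-pixel block grid has only 2×2 full
blocks, so the 4-point Spearman statistic is coarse (it can only take a
handful of values); the 30-pixel grid (16 blocks) gives the more stable
rank statistic, and the slope sign is the robust quantity at every size.

## 6. The synthetic study area

The generator emulates the *structure* of the real inputs, not their
radiometry.  Defaults describe the emulated conditions: a 120×120 km
domain at 1 km; reflectance at 1/7 km with 10 bands; up to 15 species;
19 study years (2000–2018); dry season Jan–Apr + Nov–Dec; an aridity
gradient from 0.2 (semi-arid) in the west to 1.0 (humid) in the east;
climate/drought grids on 20-km cells so the domain spans 6×6 climate
cells (preserving, at desk scale, the real-study ratio of domain size to
half-degree climate cells).

* **Diversity field D**: Gaussian-blurred white noise (blur radius 8
  cells) rescaled to [0, 1].
* **Reflectance**: each fine pixel draws one signature from the local
  pool of the first k = 1 + round(D·14) species, plus sensor noise
  (sd 0.01).  The signature table places species at increasing spectral
  distance from the community centroid (random per-band sign patterns,
  linearly growing amplitude, jittered).  This graded construction makes
  the prefix-pool spread grow steadily over the whole k range; a plain
  uniform-random table concentrates its variance in the first two or
  three species, saturating the CV response and making rank recovery of
  D fragile to the particular table drawn.  Ecologically it encodes that
  the species added in richer stands are the spectrally more distinct
  ones.
* **Drought index**: per climate cell, a monthly AR(1) proxy (φ = 0.5)
  mixing a shared regional series (weight 0.7) with a local one, plus a
  shared interannual component (amplitude 0.3) that creates coherent
  drought/wet years.  The proxy is standardized per calendar month over
  a 1990–2018 *calibration* window, while the study stacks cover
  2000–2018 only — mirroring how published SPEI products are calibrated
  on a much longer record than any study period.  A drying trend with
  amplitude 1.5 sd (over the calibration span) at the arid end and 0 at
  the humid end then makes the study window register elevated drought
  frequency in arid cells (~0.45 vs the ~0.31 a trend-free standardized
  index shows at the −0.5 threshold).  Without a longer calibration
  window, per-window standardization forces drought frequency to be
  spatially flat and no frequency gradient can exist.  Consequence: the
  study-window per-month moments are (0, 1) only where the trend is
  ~zero; the humid edge is where that textbook property is asserted.
* **Sensitivity field**: s = clip(0.7 − b(AI)·D + N(0, 0.03²), 0, 0.95)
  with benefit slope b(AI) = 0.8·(1.05 − AI) clipped to [0, 0.8]:
  diversity lowers sensitivity everywhere, twice as strongly at the arid
  end as at mid-gradient, nearly not at all at the humid end.
* **VI series**: VI = μ_i + 0.05·u with a seasonal sinusoid μ_i ∈ [0.3,
  0.8] peaking in August, u = c·z + √(1−c²)·ε, z the cell's 1-month
  index, c = s in dry months and 0.1·s otherwise.  Coupling is planted
  on the 1-month scale only; 3/6-month couplings emerge through the
  trailing-mean construction.
* **Mask, zones, richness**: 90% random forest cover; a 4×4 grid of
  rectangular pseudo-counties; richness = Σ k over zone cells with 5%
  noise.

Everything is a pure function of the config seed (streams are keyed per
artifact with CRC32-stable keys), so identical configs give identical
bytes across runs and platforms.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sensor radiometry and band
correlation, orbital/QC artifacts, topographic and phenological
structure beyond a sinusoid, spatially structured land-cover, real
county geometries, and any mechanism linking diversity to sensitivity
other than the planted linear one.  Recovery tests demonstrate that the
*pipeline* measures what it claims to measure, not that the ecological
conclusion holds in any particular real landscape.

## 7. Problem sizes and runtime

The test and reproduction runs use the default 120×120 km domain (fine
grid 840×840×10 bands, ~3.3 M VI values), which exercises every stage at
full parameter settings while keeping a complete end-to-end run below
ten seconds; estimator-recovery experiments use 8×8 domains with one
climate cell per pixel so replicate pixels carry independent drought
series.

## 8. Known limitations

* Correlation is the only coupling metric; no lagged or partial
  correlations, and no event-anatomy resistance/recovery indices.
* No reprojection: all grids are axis-aligned on one coordinate system.
* Block correlations ignore spatial autocorrelation within blocks, so
  their p-values are optimistic (as is standard for this windowed
  design); the package reports them but draws no conclusions from them.
* The county-richness stage defines the data contract and validates
  against synthetic zones; real survey correlations require external
  data the package does not ship.
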