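# Methods

This note records the scientific and numerical choices behind
`topomosaic`: the models it fits, the synthetic data it validates them on,
and the places where the design was genuinely open.

## Problem and approach

Within a forest–savanna mosaic landscape, climate is effectively constant,
so the local arrangement of closed (forest) and open (savanna) tree cover
must be explained either by self-reinforcing vegetation–fire feedbacks or
by fixed environmental heterogeneity, of which terrain is the dominant
source.  The package operationalizes this contrast as a prediction task:
classify each pixel's vegetation state from topographic features alone.
Under pure feedbacks the achievable accuracy is 0.5 (chance, on balanced
samples); every point above 0.5 quantifies topographic determination.

## Pipeline stages

**Terrain features.**  Six per-pixel predictors are derived from
elevation:

- `TPI_r` for r = 50, 500, 5000 m: elevation minus the mean elevation in a
  square box window of side `2·round(r/cell) + 1` pixels, centre included,
  edges mirrored.  The box (rather than disc) window and the
  centre-included mean are the semantics of a uniform filter; "radius"
  therefore sets the half-side.  Positive values are crests, negative
  values depressions, at the given scale.
- `slope`: Horn's 3×3 finite-difference gradient (the default of GRASS
  `r.slope.aspect`), reported in degrees.
- `aspect_sin`, `aspect_cos`: eastness and northness of the downhill
  direction.  Flat cells (zero gradient) receive (0, 0) as a documented
  sentinel rather than nodata, so no pixel drops out of the feature vector
  for being flat.

Nodata handling: TPI means exclude masked cells (mask-weighted box
filter); slope/aspect are invalidated wherever any cell of the 3×3 stencil
is masked.  All three operators are verified against literal per-pixel
loop implementations to 1e−9 relative tolerance.

**Landscape classification.**  Percent cover is binarized at 65 % by
default — the minimum between the open and closed modes of the bimodal
cover distribution in the region the pipeline emulates.  A detector
(`find_bimodal_threshold`) can instead locate that minimum from data: a
Gaussian KDE with Scott's-rule bandwidth, evaluated on a 0.1-unit grid;
the threshold is the density argmin between the two highest local maxima,
and unimodal input raises an error so callers can fall back to the fixed
value.  Boundary conventions (the distribution's tails make these
material, and they are tested explicitly): *closed* requires cover
strictly above the threshold; mosaic bounds are inclusive,
0.05 ≤ fraction_closed ≤ 0.95; tiles with fraction_valid < 0.75 are
excluded; class fractions are computed over valid pixels while
fraction_valid is over all tile pixels; trailing partial tiles are dropped
rather than padded, to avoid biased fractions.

The pipeline runs in a projected local frame with constant metres per
pixel; the 0.1° landscape of the emulated study design becomes a
configurable square tile (333 px at 30 m/px ≈ 10 km).  Landscape roughness
is the population standard deviation of valid elevation within the tile.
Coarse covariates (e.g. climate) aggregate to tiles by the arithmetic mean
of valid cells; grids are matched by nearest-cell-centre resampling with
nodata propagation.

**Sampling and models.**  The regional model pools 5 open + 5 closed
pixels per mosaic landscape (uniform, without replacement), so it learns
within-landscape configuration rather than between-landscape composition;
local models draw 5000 balanced pixels from their own tile.  Where a class
runs short, both classes shrink to the minority count to preserve balance,
and tiles with fewer than 50 minority pixels are skipped with a recorded
reason (the 50-pixel floor and the cap-and-balance rule are this package's
policy; they keep degenerate fits out of the summaries while logging what
was dropped).  Splits are stratified 80/20, also per local model.  The
classifier is a 100-tree random forest with ≥ 10 samples per leaf and
depth ≤ 10 (scikit-learn engine; remaining hyperparameters are engine
defaults, recorded in the run manifest).  Reproducibility: one master seed
fans out to per-tile substreams by mixing the tile id into a
`SeedSequence`, so any tile's sample and fit can be regenerated
independently of iteration order.

**Effect summarisation.**  First-order ALE is implemented from its
definition: 20 quantile bins per feature (duplicate edges merged, weights
pooled), mean finite difference of P(closed) across each bin's edges with
the other features held at observed rows, accumulated and centred to a
count-weighted mean of zero.  P(closed) is the forest's soft vote.  The
per-feature, per-landscape *effect direction* is the Spearman correlation
of bin centres versus ALE values — one unweighted point per bin, mirroring
a correlation "of the plot" — and an absolute-value variant
(ρ(|centre|, ALE)) captures symmetric V-shaped responses.  Degenerate
(constant-feature or flat) curves are flagged and report direction 0
rather than erroring, so per-tile sweeps always complete.  The ALE
implementation is checked against a double-loop oracle to 1e−12 and
recovers the slope of a closed-form linear-probability model within 5 %.

## Synthetic landscapes

The generator defines the conditions under which the pipeline is
validated; its defaults are fixed once and used throughout the tests.

- **Terrain**: Fourier synthesis of a Gaussian random field with power-law
  spectrum P(f) ∝ f^−β; β (default 2.5) sets smoothness, and the field is
  rescaled so its standard deviation equals the requested amplitude
  (default 20 m) exactly.  Cell size defaults to 30 m.  FFT periodicity
  artefacts are accepted because tiles are analysed locally.
- **Vegetation**: a latent-threshold logistic model on the z-scored
  features, `state = 1{η + ε > 0}` with
  η = intercept + Σ c_f·z(f) and ε i.i.d. logistic with scale `noise_sd`.
  Marginally this is Bernoulli(logistic(η / noise_sd)): at `noise_sd = 1`
  (the default) the textbook logistic-regression generating process, at
  `noise_sd = 0` the deterministic limit (exact ties broken by a fair
  coin).  The noise scale therefore dials the attainable accuracy ceiling
  continuously from chance to 1, which is what makes planted-driver
  recovery testable at a known ceiling.  Standardizing features before
  applying coefficients makes "which feature dominates" well-defined
  ground truth.  Optionally the noise is a smoothed Gaussian field
  (matched standard deviation) so errors form spatial patches.  Percent
  cover is then drawn from a two-mode normal mixture conditioned on the
  state (defaults 15 % and 90 %, sd 5 %), clipped to [0, 100]; with modes
  ≥ 4 sd apart, thresholding at the midpoint recovers ≥ 99 % of states.
- **Feedback-only mode**: smoothed white noise thresholded at the quantile
  matching the target closed fraction — a patchy binary field with
  patches of a chosen scale, statistically independent of any elevation
  raster.  `patch_scale ≤ 1` degenerates to i.i.d. Bernoulli.

What the generator does *not* emulate: drainage networks and other
hydrological structure, fire-spread dynamics, anisotropic relief, real
DEM error models, and the climate gradients that drive between-landscape
composition.  Passing tests therefore demonstrate that the pipeline's
operators are correct and that it recovers known drivers and respects
nulls under controlled conditions — not that topography explains any
particular real landscape.

## Numerical choices and degenerate inputs

- Quantile bin ties in ALE are merged; a fully constant feature yields a
  flagged single-bin zero curve.
- Tiles whose forest cannot be fitted (single-class samples after
  masking) are recorded as skipped, never silently dropped.
- `top_feature` breaks importance ties lexicographically.
- Composition subsets ("mostly open / balanced / mostly closed") split
  mosaic landscapes at fraction_closed = 1/3 and 2/3 by default;
  the bounds are configurable because no canonical definition exists.
- Raster formats: single-band TIFF with grid metadata (cell size, origin,
  nodata) in the image description, and a headered ASCII grid for small
  human-readable fixtures.  Reprojection between coordinate systems is
  out of scope.
- All randomness flows from explicit integer seeds; a full pipeline run
  writes a manifest with content hashes of every output, and reruns under
  the same configuration are bitwise identical.

## Problem sizes

The test suite and the calibration script run on deliberately small
worlds chosen to estimate each property well: 50×50 grids for operator
oracles; 4–20 tiles of 64–128 px for pipeline properties; the
chance-level calibration uses 24 replicate landscapes of 64×64 px with
1000 balanced samples each (standard error of the mean accuracy ≈ 0.007,
comfortably resolving the ±0.02 band around 0.5).  The demo
configuration (6 tiles of 128×128 px) exercises every stage end to end.

## Known limitations

- Nearest-neighbour alignment only; no area-weighted aggregation of
  fractional covers across very different resolutions.
- The regional/local contrast is implemented, but with synthetic data the
  interesting regional-vs-local accuracy gap only appears when drivers
  vary across tiles (as in the opposing-sign cancellation test); the
  package does not claim the real-world gap.
- Impurity-based importances are biased toward high-cardinality features;
  all six features here are continuous, which limits but does not remove
  the concern.  Effect directions from ALE are the more robust summary.
- The bimodality detector assumes exactly two meaningful modes;
  multi-modal cover distributions return the minimum between the two
  strongest modes only.
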