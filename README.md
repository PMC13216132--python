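# topomosaic

Tools for asking how much of the fine-grained arrangement of forest and
savanna inside a mosaic landscape is set by topography.

In the tropical transition zones, closed-canopy forest and open savanna
co-occur as sharp-edged patches within landscapes of roughly 10 × 10 km.
Two explanations compete: vegetation–fire feedbacks that make both states
self-maintaining under identical conditions (bistability), and fixed
environmental heterogeneity — above all terrain — that decides locally which
state can persist.  The two are distinguishable: if feedbacks alone placed
the patches, a classifier predicting vegetation state from topography alone
would score at chance (accuracy 0.5); the further above chance it scores,
the more of the configuration is topographically determined.

`topomosaic` implements that test as a reusable pipeline:

1. **Terrain features.**  From an elevation raster it derives six
   predictors per pixel: the topographic position index
   TPI_r = z − mean(z, within radius r) at r = 50, 500 and 5000 m
   (box-window means, uniform-filter semantics), slope from Horn's 3×3
   gradient, and the eastness/northness components sin(aspect),
   cos(aspect) of the downhill direction.
2. **Landscape classification.**  Percent tree cover is binarized at a
   threshold (default 65 %, the minimum between the open and closed modes
   of the cover distribution; a KDE-based detector can locate it from the
   data).  The grid is tiled into landscapes; a tile is a *mosaic* when
   both class fractions lie in [0.05, 0.95], *homogeneous* otherwise, and
   *excluded* when fewer than 75 % of its pixels are valid.
3. **Models.**  A *regional* random forest (100 trees, ≥ 10 samples per
   leaf, depth ≤ 10) is fitted to 5 open + 5 closed pixels per mosaic
   landscape, and a *local* forest per landscape to 5000 balanced pixels,
   each evaluated by accuracy on a stratified 80/20 held-out split.
4. **Effect summaries.**  Each feature's influence is an Accumulated Local
   Effects (ALE) curve of the predicted P(closed); curves are reduced to a
   per-landscape *effect direction*, the Spearman correlation ρ(feature
   bin, ALE value), whose sign gives the direction of the effect and whose
   magnitude its monotonicity.

A synthetic-landscape generator (spectral terrain with power-law spectrum;
vegetation from a latent logistic model on the standardized features; a
feedback-only patchy mode independent of terrain) provides ground truth for
every stage, so driver recovery, direction signs and chance-level null
behaviour are all testable.

## Worked example

```python
from topomosaic import synthetic, model

elev = synthetic.generate_elevation(synthetic.TerrainSpec(shape=(192, 192), seed=1))
veg = synthetic.VegetationSpec(coefficients={"TPI_500m": -5.0}, noise_sd=0.5, seed=1)
labels, percent = synthetic.generate_vegetation(elev, veg)

res = model.MosaicTopographyModel(percent, elev, tile_size=96,
                                  n_local_total=2000).fit(seed=1)
print(res.summary())
```

```
Mosaic topography analysis
============================================================
tiles: 4  tile size: 96 px  cover threshold: 65%
landscape classes: mosaic=4
------------------------------------------------------------
regional model:  accuracy 1.000  (n=40)
  top feature: TPI_500m
  importances: TPI_50m=0.253, TPI_500m=0.293, TPI_5000m=0.213, slope=0.067, aspect_sin=0.120, aspect_cos=0.053
  effect directions: TPI_50m=-0.93, TPI_500m=-0.93, TPI_5000m=-0.95, slope=+0.93, aspect_sin=-0.85, aspect_cos=+0.70
------------------------------------------------------------
local models: 4 fitted, 0 skipped
  mean accuracy 0.933; share > 0.625: 1.00
  top-feature counts: TPI_500m=4
============================================================
```

The vegetation here was generated with a single negative coefficient on
TPI_500m (closed cover in local depressions) plus mild noise.  The fit
recovers exactly that: every local model picks TPI_500m as its top feature,
its effect direction is strongly negative (≈ −0.93), local accuracies are
well above the 0.5 chance level, and the correlated TPI scales inherit the
same negative direction.  On feedback-only vegetation the same pipeline
drops to accuracy ≈ 0.5 (see the test suite).

The `topomosaic` command exposes the stages individually
(`simulate`, `features`, `classify-landscapes`, `fit-regional`,
`fit-local`, `summarize`, `make-fixtures`) and end to end
(`run-all --config demo.cfg`), writing a manifest with content hashes so
reruns can be verified bit for bit.

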