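# fusionyield

Field-scale crop monitoring from paired fine- and coarse-resolution NDVI
imagery, as a reusable pipeline:

- **`io_grid`** — GeoTIFF/GeoJSON I/O on square-pixel north-up grids,
  integer-ratio block aggregation and nearest-neighbour resampling, NDVI
  computation, band-mapping metadata.
- **`fsdaf`** — six-stage flexible spatiotemporal fusion: predict a fine
  NDVI image at a target date from one fine reference image plus coarse
  images at the reference and target dates (class-wise temporal
  unmixing, thin-plate-spline spatial prediction, guided residual
  distribution, similar-neighbour refinement).
- **`mdi`** — Mixed Degree Index: a per-plot score in [0, 1] summing,
  over the coarse pixels overlapping a plot, the product of an
  area-based purity term `(s_p/s_w)(s_p/s_y)` and the relative
  coarse/fine NDVI discrepancy `|m − l| / max(m, l)`; 0 means pure,
  consistent pixels.
- **`phenology`** — per-plot NDVI time series, daily linear
  interpolation, finite-difference derivatives, and selection of
  early/middle/end reference dates plus the season peak.
- **`yield_model`** — yield-monitor cleaning (moving-window 3-SD rule),
  0.5 m rasterisation, NDVI/yield pairing, ordinary-least-squares yield
  model with R²/RMSE, and per-date correlation curves.
- **`synthetic`** — seeded scene generator with known ground truth: crop
  plots and background covers on logistic seasonal curves, coarse
  stacks as exact block means plus optional noise, and yield linear in
  peak NDVI.
- **`experiments`** — seeded benchmarks comparing reference dates and
  coarse ratios against retained fine truth.

## Command line

```sh
# generate a synthetic scene (GeoTIFF stacks, plots.geojson, yield.csv, truth/)
fusionyield simulate --config scene.yaml --outdir scenes/

# fuse one date
fusionyield fuse --fine-t1 F.tif --coarse-t1 C1.tif --coarse-t2 C2.tif \
    --ratio 8 --out fused.tif --classes 4 --similar 20 --seed 0

# per-plot mixing diagnostics
fusionyield mdi --plots plots.geojson --coarse C.tif --fine F.tif --out mdi.csv

# stage selection from a date-indexed stack
fusionyield phenology --stack fine_stack.yaml --plots plots.geojson --out stages.csv

# yield-monitor cleaning and the NDVI-yield fit
fusionyield yield-clean --in yield.csv --window 21 --out clean.csv
fusionyield yield-fit --ndvi fused.tif --yield yield.csv --plot plots.geojson --out fit.json

# full pipeline with a JSON manifest of every artifact
fusionyield run --config scene.yaml --outdir out/ --seed 0
```

`scene.yaml` mirrors the `SceneConfig` fields (`fine_shape`, `ratios`,
`doys`, noise levels, yield coefficients, and optionally full
`covers`/`regions`/`plots` definitions with rectangles as
`[xmin, ymin, xmax, ymax]`); omitted fields fall back to the default
three-plot layout.

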