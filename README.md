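# gtwrkit

Spatiotemporal regression toolkit for small region-year panels, built for
epidemiological settings where an outcome rate (e.g. police-reported
domestic violence per 10,000 population across ~13 regions over ~3 years)
may relate to socioeconomic covariates differently in different places
and years — and where the recorded outcome may understate the truth.

The core method is **geographically and temporally weighted regression
(GTWR)**: every region-year observation i gets its own coefficient vector

    β̂_i = (Xᵀ W_i X)⁻¹ Xᵀ W_i y,
    w_ij = exp(−d_ij²/2b²) · exp(−|t_i − t_j|/h),

a product of a fixed Gaussian spatial kernel (bandwidth b, km) and an
exponential temporal decay (bandwidth h, years), with (b, h) selected by
minimizing the corrected AIC of the fitted smoother,
AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S).

Around it, the toolkit provides the full study workflow:

- `gtwrkit.synth` — synthetic region lattices (Voronoi tessellation of a
  180 × 60 km rectangle), correlated standardized covariate panels,
  spatially varying true coefficient surfaces, outcomes, and monthly
  activity streams with a lockdown pulse;
- `gtwrkit.preprocess` — rates per 10,000, z-score and min-max scaling;
- `gtwrkit.isolation` — a composite log-scale isolation index contrasting
  residential vs. non-residential mobility, electricity, and movement
  range, I = Σ ln X^R − Σ ln X^C;
- `gtwrkit.weights` / `gtwrkit.moran` — Queen/Rook/kNN spatial weights,
  global Moran's I with permutation inference, local Moran (LISA) with
  HH/LL/HL/LH cluster classification;
- `gtwrkit.global_models` — OLS baseline, VIF, seeded cross-validated
  LASSO, Breusch–Pagan heteroscedasticity test;
- `gtwrkit.sensitivity` — underreporting scenarios Y(x) = Y/(1 − x) with
  frozen bandwidths, sign-stability accounting, and standardized offsets
  ΔX^offset = −ΔY/β in SD units;
- `gtwrkit.pipeline` / a `gtwrkit` CLI — end-to-end orchestration with a
  JSON run report.

See `docs/methods.md` for the model conventions and design choices.

## Worked example

```python
import json
from gtwrkit import pipeline

report = pipeline.run(pipeline.RunConfig(seed=1, outdir="demo_run"))
print(report["bandwidths"])
print(json.dumps(report["model_comparison"], indent=2))
```

prints (numbers from this exact run):

```
{'b_km': 53.72711573084984, 'h_years': 19.990281712162012}
[
  {
    "model": "OLS",
    "r2": 0.4499111890416446,
    "adj_r2": 0.3032208394527499,
    "aicc": 111.7591105474248,
    "rmse": 0.7094450170277489
  },
  {
    "model": "GTWR",
    "r2": 0.8566415500627118,
    "adj_r2": 0.7713039337480165,
    "aicc": 89.2939158507699,
    "rmse": 0.36217126105256103
  }
]
```

The synthetic truth has spatially varying coefficients, so the local
model fits far better than the global one: R² rises from 0.45 to 0.86 and
RMSE falls from 0.71 to 0.36. The selected spatial bandwidth (~54 km on a
180 km-wide lattice) says influence is regional, not island-wide, while
the wide temporal bandwidth (~20 years over a 2-year span) says the three
annual cross-sections are pooled almost uniformly in time. The same
report carries the Moran's I table per weights method and year, VIF and
LASSO screening (the built-in collinear covariate pair shows VIF ≈ 12–14
and gets partially zeroed), the Breusch–Pagan statistic, the per-predictor
local-coefficient summary, the underreporting sensitivity table (every
`pct_same_sign` is 100.0 — refitting a linear smoother on y/(1 − x) with
frozen weights rescales coefficients by 1/(1 − x) and cannot flip a
sign), and the standardized offset table.

Command-line equivalents:

```
gtwrkit synth --outdir demo          # geometries + panel + streams
gtwrkit run --seed 1 --outdir demo_run
gtwrkit gtwr demo/regions.geojson demo/panel.csv --bw-select
gtwrkit sensitivity demo/regions.geojson demo/panel.csv \
    --bw-spatial 60 --bw-temporal 2 --underreporting 0.10,0.25,0.40
```

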