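# Methods

## The model

`gtwrkit` analyses a small panel of contiguous regions observed at a few
annual time points — the canonical setting is 13 police-region analogues
over 3 years, i.e. n = 39 region-year observations. The outcome y_i(t)
(an incidence rate, standardized) is related to standardized covariates
x_ik through a locally varying linear model:

    y_i(t) = β_i0(t) + Σ_k β_ik(t) x_ik + ε_i

Each observation gets its own coefficient vector, estimated by weighted
least squares centred on that observation:

    β̂_i = (Xᵀ W_i X)⁻¹ Xᵀ W_i y

W_i is diagonal; its entries are the product of a fixed Gaussian spatial
kernel and an exponential temporal decay:

    w_ij = exp(−d_ij² / 2b²) · exp(−|t_i − t_j| / h)

with d_ij the centroid distance in km, b the spatial bandwidth (km) and h
the temporal bandwidth (years). The product form (rather than a unified
space-time distance with a scale ratio) is the package's definition of
spatiotemporal proximity: space and time decay independently and an
observation's self-weight is always 1 (no leave-one-out; the hat matrix
therefore has positive diagonal and tr(S) ∈ [p+1, n]).

Bandwidths are chosen by minimizing the corrected Akaike criterion of the
fitted linear smoother,

    AICc = 2n ln σ̂ + n ln 2π + n (n + tr S)/(n − 2 − tr S),  σ̂ = √(SSR/n),

over a log-spaced 15 × 15 grid spanning [0.1, 10] × the maximum pairwise
centroid distance and [0.25 years, 10 × the time span], followed by
golden-section refinement one axis at a time around the grid minimum.
The search is deterministic, the full AICc surface is returned for
inspection, and the refined point is never accepted if it is worse than
the grid minimum. Grid points where n − 2 − tr(S) ≤ 0 (bandwidths so
small that effective degrees of freedom are exhausted) are treated as
undefined; if every point is undefined the selection fails loudly.

As b, h → ∞ all weights go to 1 and every local fit collapses to the
global OLS solution with tr(S) → p + 1; this limit is asserted in the
test suite at b = h = 10⁹ to 10⁻⁶.

### Conventions that the literature leaves open

- **Local standard errors**: SE(β̂_ik) = √(σ̂²_eff · [C_i C_iᵀ]_kk) with
  C_i = (XᵀW_iX)⁻¹XᵀW_i and σ̂²_eff = SSR/(n − tr S) (residual variance on
  effective degrees of freedom). Pseudo-t = β̂/SE; the default
  significance cutoff for "percent of regions significant" is |t| ≥ 1.96.
- **Adjusted R² for the local model**: 1 − (1 − R²)(n − 1)/(n − tr S),
  the effective-parameter analogue of the OLS formula.
- **OLS AICc** uses the same hat-trace formula with tr(S) = p + 1, so the
  global and local models are scored on one scale.
- **Coefficient strength bins** for mapping: zero = none; (0, 0.25) weak,
  [0.25, 0.5) moderate, [0.5, 1) strong, ≥ 1 very strong, mirrored for
  negative values. Bins are right-open so each value has one label.
- **t statistics, not z**: at n = 39 the normal approximation is
  materially anti-conservative, so the OLS table reports t on n − p − 1
  degrees of freedom and labels it as such.

## Spatial autocorrelation

Global Moran's I is computed exactly as

    I = N Σ_ij w_ij (x_i − x̄)(x_j − x̄) / (S0 Σ_i (x_i − x̄)²)

and tested by random relabelling (999 permutations by default, seeded),
with the two-sided pseudo p-value measured as deviation from the null
expectation E[I] = −1/(N−1). Weights are Queen contiguity (any shared
boundary point), Rook (shared positive-length segment), or kNN (k = 4 by
default, asymmetric, distance ties broken by lowest region index), all
row-standardized by default — the convention of the mainstream
cluster-mapping tools. Boundary detection snaps at 10⁻⁹ km to tolerate
floating-point tessellation output.

Local Moran's I_i = z_i (Σ_j w_ij z_j)/m2 uses m2 = Σ z²/n (the original
LISA scaling, so Σ_i I_i reproduces the global statistic up to the S0
factor). Inference is by conditional permutation: z_i is held fixed and
its neighbors' values are drawn without replacement from the remaining
z's. Cluster classes HH/LL (clusters) and HL/LH (outliers) follow the
quadrant of (z_i, spatial lag), gated on p_i ≤ α = 0.05. Note that with
very few regions the conditional-permutation p has a hard floor (there
are only so many distinct neighbor draws), so sparse maps at small n are
expected behaviour, not a bug.

## Isolation index

Six monthly percent-change-from-baseline streams — residential and
commercial variants of mobility (M), electricity consumption (E) and
movement range (R) — are converted to levels X = 1 + p/100 and combined
as

    I(t) = ln X_M^R + ln X_E^R + ln X_R^R − ln X_M^C − ln X_E^C − ln X_R^C.

Residential streams carry sign +1 (more time at home = more confinement),
non-residential −1. A baseline month (p = 0 in every stream) contributes
exactly 0; swapping the residential and commercial streams negates the
index pointwise. The log-level form keeps the index well-defined for any
percent change above −100 and makes the contributions additive, which the
stored per-component decomposition exposes.

Internal consistency is summarized by the Pearson correlation matrix of
the standardized streams, and external relevance by the Pearson
correlation (with a t-reference p-value) between the monthly index and a
monthly outcome series. When the island-wide monthly index enters the
annual regression as a covariate, it is aggregated to calendar-year means
and applied uniformly across regions — the only reconstruction consistent
with a single region-invariant index series.

## Underreporting scenarios and offsets

If recorded counts represent only (1 − x) of the underlying reportable
volume, the adjusted outcome is Y(x) = Y/(1 − x), with x ∈ {0.10, 0.25,
0.40} by default. Covariates and — deliberately — the kernel bandwidths
are held at their baseline values during scenario refits: the weighting
scheme is part of the specification being stress-tested, and freezing it
makes the analysis exactly interpretable, because any linear smoother
refit on c·y returns c·β̂. Consequently scenario coefficients equal
baseline/(1 − x) to machine precision and sign stability is exactly 100%;
the scenario machinery verifies that the fitted models actually behave
this way rather than assuming it. (Re-optimizing bandwidths per scenario
would break this exactness; it is intentionally not done.)

The offset calculus converts local coefficients into SD units: a shift
ΔX_k in a standardized predictor moves the modeled outcome by
ΔY ≈ β_k ΔX_k, so the standardized change that counterbalances a modeled
outcome change is ΔX_k^offset = −ΔY/β_ik per region. The default step is
ΔX = 0.5 SD. Offsets are computed from the per-region local coefficients
(not the mean — the reported P25/median/P75 would otherwise be
degenerate); regions with β exactly 0 are excluded and counted.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the method assumes:

- **Geometry**: Voronoi cells of jittered grid points clipped to a
  180 × 60 km rectangle (an elongated-island aspect). Voronoi cells tile
  the rectangle, so contiguity is guaranteed and shapes are irregular.
  Coordinates are planar km directly — no geographic CRS — so kernel
  bandwidths are in km by construction.
- **Covariates**: 8 standardized draws from a multivariate normal with
  exchangeable correlation 0.3 and one deliberately collinear pair
  (ρ = 0.95), giving the VIF/LASSO screens realistic redundancy to find.
- **Truth**: coefficient surfaces β(u, t) = a + b·ũ + c·(t − t₀), with ũ
  the west-east centroid coordinate rescaled to [−1, 1]; the default plan
  includes one predictor whose sign flips from west to east and one with
  temporal drift.
- **Outcome**: the exact local linear predictor plus N(0, σ²) noise,
  σ = 0.25 by default (a noise-to-signal level at which the method should,
  and does, recover the surfaces); σ = 0 gives exact-recovery fixtures.
- **Component streams**: a half-sine lockdown pulse (residential +20%,
  commercial −45%, magnitudes typical of 2020 mobility reports) plus
  2%-sd noise.

It does **not** emulate count-valued outcomes (no Poisson structure),
region-varying reporting behaviour, population-size heteroscedasticity,
spatially correlated noise, or real Puerto Rico geography. Passing tests
therefore demonstrate that the estimator recovers the model it assumes
under Gaussian noise — not that the model is correct for any particular
real dataset.

## Problem sizes and determinism

Default analyses run at 13 regions × 3 years (n = 39), 999 permutations
for Moran tests, and 20 replicate panels for the parameter-recovery
check; these sizes keep every quantity estimable in seconds while
matching the regime the method is designed for. Every stochastic step
takes an explicit seed (NumPy `default_rng`), and regenerating with the
same seed reproduces byte-identical tables.

## Known limitations

- Fixed (not adaptive) spatial bandwidth; Gaussian/exponential kernels
  only; no mixed global-local terms; no prediction at unobserved sites.
- The AICc surface at n = 39 is shallow near its minimum, so selected
  bandwidths can vary noticeably between noise realizations even when
  fitted surfaces barely differ.
- Permutation p-values have resolution 1/(n_perm + 1) and, for local
  statistics at small n, a combinatorial floor well above conventional α.
- The isolation index is a population-confinement proxy built from
  aggregate streams; it measures neither interpersonal isolation nor any
  individual-level quantity.
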