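# Methods

## Problem and model

Several global gridded population products disagree substantially — each
inherits the biases of its disaggregation strategy (administrative-uniform
spreading, built-up-area reallocation, nighttime-light blooming, ambient
redistribution, covariate regression). `popfuse` fuses such products into a
single annual count surface in four stages.

**1. Harmonization.** All layers must share one regular WGS84 lattice; no
resampling is performed (silently resampling count rasters corrupts totals).
Density layers are converted to counts with a surface-area layer; when none
is supplied, cell areas come from the spherical band formula
A = R² (λ₂−λ₁)(sin φ₂ − sin φ₁) with R = 6371.0072 km. Products released at
5–10-year cadence are completed per pixel by piecewise linear interpolation
between the bracketing native-year knots,

    y = y₁ + (y₂ − y₁)·(t − t₁)/(t₂ − t₁),

and linear extrapolation from the two nearest knots outside the native range.
The bracketing pair (not a global line) is used when more than two knots
exist; a pixel that is nodata in any knot year stays nodata in every filled
year, so interpolation never fabricates populated cells. Negative
extrapolated values survive until the adjustment stage.

**2. Reliability screening.** For every (product, year), each country's
product total Y is scored against the census total X with four errors:
APE = (X−Y)/X, SE = (X−Y)², SLE = (ln(1+X) − ln(1+Y))², Dif = Y−X. Each
metric is min-max scaled to [0,1] within its (product, year) group, and a
k = 2 K-means (Lloyd, Euclidean, 50 seeded restarts, 300 iterations)
partitions countries in scaled (|APE|, SE, SLE, |Dif|) space. Magnitudes are
used for clustering and for the decision rule so over- and under-estimation
are penalized symmetrically; the signed values stay in the table. The
cluster whose centroid has the smaller Euclidean norm is the reliable
("valid") one; a norm tie marks both clusters valid, favoring inclusion.
Clustering is run independently per (product, year) because the validity
bookkeeping is per product per country-year. k is fixed at 2 by default;
`choose_k` (silhouette-maximizing, ties to smaller k) is kept as a
diagnostic. Countries with zero census leave APE undefined and are excluded
from the features (flagged invalid).

**3. Fusion.** The fused estimate for year t is the intercept-free blend
Y_t = Σₙ a_{n,t} X_{n,t} + ε_t with a_{n,t} ≥ 0. No intercept keeps
zero-population pixels at zero; non-negativity keeps the blend
interpretable and the surface sign-correct. Weights are trained at the
national level on countries where *every* product of the year's epoch is
valid; the remaining countries are the held-out test set. Two objectives are
fitted with L-BFGS-B under box constraints a ≥ 0:

* GLM — Gaussian/identity squared error (the simplest family consistent
  with the additive model);
* QRM — quantile regression at τ = 0.5 (configurable) on a pinball loss
  whose kink is Huberized with half-width 1e-6 × response scale for
  quasi-Newton stability (the width is recorded in the fit report).

Model selection runs 10-fold cross-validation over up to 200 random
optimizer restarts; since both objectives are convex, restarts that land on
the same full-data optimum share one CV score and are scored once (a pure
memoization — results are identical to scoring each restart). GLM vs QRM is
decided by RMSE on the held-out test countries (ties and a config override
go to QRM, the more outlier-robust choice). The winning weights are applied
cell-wise; a cell is nodata only when every covariate is nodata, and a
missing covariate alongside present ones contributes zero (logged).
A per-pixel median composite of the products is computed as the benchmark
baseline.

**4. Adjustment.** Within each country, pixels are rescaled by
a_t = P_ref / Σ P_pixel so national totals match the reference (UN-style)
estimates. Order of operations: clamp negatives to zero *first*, then
compute and apply factors. Clamping after scaling — the literal reading of
the procedure — breaks the conservation that adjustment exists to enforce;
clamping first satisfies both stated guarantees (non-negative pixels and
exact national totals) and is therefore the default, with
`clamp_after_adjust=True` available for the literal order. Countries absent
from the reference pass through unadjusted with a warning. Density surfaces
are derived from the adjusted counts and the area grid.

## Validation statistics

* R² = 1 − Σ(xᵢ−yᵢ)²/Σ(x̄−xᵢ)², RMSE, MAE with x = census, y = prediction.
* Relative entropy: discrete KL divergence (natural log) between the
  census and predicted count distributions over the admin units compared in
  a given year; ε = 1e-12 is added to predicted cells before renormalization.
  Natural log is used because the divergence is the Kullback–Leibler form;
  values are nats.
* DTW distance between annual total curves: dynamic programming over
  monotone warping paths, absolute-difference local cost, symmetric step
  pattern with diagonal weight 2 and expansion weight 1, normalized by
  len(X) + len(Y) — the common defaults of standard DTW implementations; the
  step weights, window and normalization are configurable.
* Mann–Kendall: S = Σ_{k<j} sgn(Xⱼ−Xₖ); tie-corrected variance
  Var(S) = [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18; normalized statistic with the
  ±1 continuity correction ((S−1)/√Var for S>0, 0 at S=0, (S+1)/√Var for
  S<0); two-sided p from the normal approximation at all n. Sen's slope is
  the median of all pairwise slopes (even counts: mean of the central pair).
  `trend_map` applies both per pixel over the annual stack; pixels missing
  any year are nodata, and no multiple-testing correction is applied across
  pixels (a Benjamini–Hochberg flag exists for sensitivity analyses).

## Synthetic study system

The generator produces a fully known world so every stage is testable
without external data: Voronoi countries on a geographic lattice (default
60 × 120 cells over ±60° longitude, ±30° latitude — an honest geotransform
in degrees so the spherical area math is exercised, small enough that a full
31-year pipeline run completes in about two minutes on one CPU), truth =
Gaussian city kernels (default 3 per country, mean city ≈ 2×10⁵ people)
over a rural floor, per-country exponential growth in −1 %…+3 %/yr, and an
exact census (level-0 plus a 4-quadrant level-2 split). Five products mirror
the real suite's cadence (two ending in 2000, one 5-yearly throughout, two
annual from 2000) and apply caricature distortions — admin-uniform
smearing, built-up reallocation, urban blooming, ambient smoothing,
capped resmoothing. Their only contract is producing distinct, detectable
error structures, not emulating any real product. A planted 20 % of
(country, product) pairs carry a 3× multiplicative bias; the planted table
is the ground truth for screening recovery. Pairs are drawn outside a
reserved clean core of countries (max(n_products+3, 30 % of countries)) so a
training set exists in every year by construction. Multiplicative lognormal
pixel noise (σ = 0.05) is applied everywhere. Reference totals are truth
totals drifted ±2 % per country, making adjustment factors non-trivial and
known.

What the generator does *not* emulate: realistic settlement geography,
coastline rasterization artifacts, census-definition changes, or spatially
correlated product errors. Passing tests therefore demonstrate the
correctness of the machinery and its behavior under the planted error
model, not the accuracy of any real-world fused product.

## Numerical choices

* L-BFGS-B tolerances ftol = 1e-14, gtol = 1e-12; objectives normalized by
  the response scale so tolerances are scale-free; weights floored at 0
  after convergence and asserted non-negative after every fit.
* K-means seeded (default 20240124) with 50 restarts for determinism;
  sklearn's Lloyd implementation re-initializes empty clusters internally.
* Min-max scaling of a constant metric group maps to 0 with a warning.
* Adjustment of an empty country with zero reference uses factor 1 by
  convention; an empty country with a positive reference is an error.
* I32 count rasters round half-up on write.
* One master seed fans out to per-stage seeds via `SeedSequence.spawn`,
  recorded in the run manifest; all derived seeds are below 2³¹.

## Known limitations

* All inputs must be pre-aligned; there is no reprojection or resampling.
* Coefficients are global per year — no spatially varying weights.
* Adjustment is national (level-0) only; level-2 is used for validation.
* The normal approximation of the Mann–Kendall test is used at every
  series length; for n < 10 exact tables would be preferable.
* The QRM oracle equivalence holds to the smoothing width; exact LP
  solutions are used as the independent cross-check in tests only.
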