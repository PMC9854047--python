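# Methods notes

## Data model and preprocessing

Raw canopy spectra arrive as one reflectance curve per plot on a dense
sensor grid (the emulated sensor spans 339–1029 nm; real instruments of
this class report ~0.4 nm spacing with heavy data loss at both spectrum
edges). The pipeline treats the wavelength **window as the primary
filter**: the default 450–850 nm window removes the loss-prone edges, and
any scattered missing values that survive are simply dropped per plot
before curve fitting.

Resampling fits a **least-squares cubic B-spline** per plot (interior
knots at data-site quantiles, one per ~8 nm by default) and evaluates it
on the 4 nm center grid 450, 454, …, 850 nm — 101 bands. A least-squares
spline was chosen over a roughness-penalized smoothing spline
deliberately: the LSQ fit is a projection onto the spline space, so any
spectrum that is itself a polynomial of degree ≤ 3 is reproduced exactly
at every band center (a property the test suite checks at 1e-8), whereas
penalized smoothers with natural boundary conditions distort cubics near
the window edges. With ~1 observation per 1–2 nm, the quantile knot rule
keeps every knot span populated (Schoenberg–Whitney) and the fit is
smooth at the 4 nm reporting scale. Resampled reflectance is clamped to
[0, 1.5] (white-referenced field reflectance can mildly exceed 1);
clamping events are logged.

The response is y = ln(grain P). The log both stabilizes the variance of
concentration data and makes the normal-errors models tenable.

## Spatial structures

Plot centroids sit on a rectangular grid (default 21 rows × 6 columns =
126 plots, footprint 3.2 m × 5 m — four 0.8 m beds, 5 m long). The true
plot arrangement of the motivating trial is not public, so the grid is an
explicit emulation and fully configurable (including a queen-adjacency
switch and a layout CSV override).

Adjacency M is rook (shared edge); D_M is the row-sum diagonal. The CAR
precision (D_M − φM)/τ² is positive definite exactly for φ in
(1/λ_(1), 1/λ_(n)), the reciprocals of the extreme eigenvalues of
**D_M^{-1/2} M D_M^{-1/2}** — note the inverse square roots; the
unnormalized scaling sometimes seen in print does not produce these
bounds. On any rectangular rook grid the graph is bipartite, so the
interval is exactly (−1, 1). log det(D_M − φM) is evaluated through the
same eigenvalues (sum log d_i + sum log(1 − φλ_i)) for full-field
likelihoods; training-subset likelihoods use a Cholesky factorization of
the principal submatrix instead, never an explicit inverse.

The geostatistical model uses the isotropic exponential correlogram
H_ij = exp(−φ‖s_i − s_j‖) with φ in 1/metres and a uniform prior on
(0, 1): with neighboring plots 3.2–5 m apart, that range spans
essentially-independent to essentially-flat correlation.

## Priors

* **Coefficients.** Spike-and-slab per band:
  p(β_j | γ_j) = (1−γ_j)δ₀ + γ_j N(μ_j, ν_j), with defaults μ_j = 0,
  ν_j = 1 **on standardized predictors** (fits standardize X internally
  and back-transform draws for reporting; zeros survive the transform, so
  β_j = 0 exactly iff γ_j = 0 in every draw). The prior exclusion
  probability defaults to p(γ_j = 0) = 0.9, i.e. a prior expected model
  size of one band in ten. This is the operating regime band selection is
  meant for; a 50/50 prior in a p ≈ n problem keeps roughly 10% of the
  spurious coefficients in any given draw and demonstrably deflates the
  residual-variance posterior by 20–35%. All three values accept scalars
  or per-coefficient arrays. The intercept is always included, carries an
  effectively flat N(0, 10⁶) slab, and is excluded from selection.
* **Variances.** σ², τ² ~ IG(0.01, 0.01) (shape/rate) — weakly
  informative, conjugate.
* **Spatial dependence.** φ ~ U(0, 1) (geostatistical) or
  U(1/λ_(1), 1/λ_(n)) (CAR).

## Sampler

One sweep updates, in order: (γ_j, β_j) for every coefficient in a fresh
random permutation (random-scan reduces sticking under the strong
band-to-band collinearity); the variance component(s); φ by
Metropolis–Hastings; and the latent field w (geostatistical model only).

* The (γ_j, β_j) update integrates β_j out against the slab to get the
  Bernoulli full conditional of γ_j, then draws β_j from its conditional
  normal when included. The same code path serves all three models by
  pre-accumulating X'AX and X'Ar, where A is the identity (models 1–2) or
  D_M − φM (CAR); for the CAR model those Gram matrices are linear in φ,
  so the per-sweep refresh costs O(p²) after a one-off precomputation.
* Variance components use their inverse-gamma conditionals; the CAR
  quadratic form is r'(D_M − φM)r computed without forming the matrix.
* φ is proposed as a Gaussian random walk on logit((φ−lo)/(hi−lo)) with
  the Jacobian in the acceptance ratio, so support constraints are
  automatic. The proposal scale (default 0.25) is adapted every 50
  burn-in iterations toward a 20–50% acceptance window and frozen at the
  end of burn-in, preserving detailed balance for the recorded draws.
* w has a multivariate-normal full conditional with precision
  H⁻¹/σ² + I/τ², sampled by Cholesky; a 1e-8 diagonal jitter stabilizes
  H at small φ, and proposals whose H fails to factor are rejected.

Initialization: β = 0 (intercept at ȳ), γ ≡ 1, variances at var(y), φ at
the prior midpoint, w = 0. Chains are deterministic given the seed.
The full protocol is 100,000 iterations, half discarded, thin 5; the
reduced protocol used throughout the tests and the acceptance script is
10,000 / 5,000 / 5, which the simulation benchmark shows is ample for
these posteriors (ESS ≳ 500 for the scalar parameters).

Correctness evidence: a Geweke-style successive-conditional test (prior
moments preserved when alternating θ|y and y|θ), closed-form and
numeric-integration oracles for the single-site inclusion probability,
exact small-matrix oracles for the CAR likelihood and the latent-field
conditional, and a uniform-stationarity KS check for the φ step.

## Deviance and DIC

DIC = D̄ + p_D with p_D = D̄ − D(θ̄), θ̄ the posterior mean. The deviance
focus per model: the independent and CAR models use their marginal
likelihoods as written; the geostatistical model uses the likelihood
conditional on w, so its p_D counts the latent field. That choice makes
the geostatistical DIC comparable to how its fit is actually used for
prediction, but it is a focus choice, not a theorem — comparisons across
the two focuses should lean on the CAR/independent contrast, which the
benchmark shows DIC gets right (CAR preferred on CAR-generated data).

## Cross-validation and spatial prediction

Repeated random holdout: 25 test plots, 101 training plots, 5 repeats,
splits shared across models and vegetation indices. Training fits see
only training rows; for the CAR model the training likelihood is the
principal submatrix of the full-field precision (with full-field row
sums), which is itself a valid Gaussian, and held-out plots re-enter only
at prediction time through the partitioned joint normal:
X_test β̂ − Q₂₂⁻¹Q₂₁(y_train − X_train β̂) with Q = D_M − φ̂M (τ̂² cancels).
The geostatistical model kriges the latent field:
X_test β̂ + H₂₁H₁₁⁻¹ŵ. Predictions are plug-in at posterior means,
matching the point-estimate usage the tables report; both formulas are
verified against brute-force joint-normal conditioning on every layout
with n ≤ 6.

The three reporting criteria — all bands, PIP ≥ 0.6, most probable
submodel — are realized by **refitting** on the restricted band set with
selection disabled (the restricted columns would otherwise reuse chains
whose posterior conditions on a different design). An empty selected set
degrades gracefully to an intercept-plus-spatial model.

## Vegetation-index baselines

SR, NDVI, GNDVI, SAVI, OSAVI as printed in the agronomy literature this
package tracks, including the two quirks: (i) range subscripts such as
R_{800–900} are band-mean reflectances truncated to the available grid
(800–850 on the default window; the truncation is logged), and (ii) SAVI
and OSAVI apply their 1.5/1.16 factor to the first numerator term only,
as printed; `canonical_savi=True` switches to the textbook whole-difference
forms. Point subscripts map to the nearest band center, ties to the lower
center (800 nm → 798). Indices are scored by the Pearson correlation of
the raw index with y on the shared test sets — Pearson r is invariant to
linear calibration, so refitting a univariate regression would change
nothing. The headline comparison is 100·(r̄_CAR − mean of the five index
r̄'s), in percentage points.

## Synthetic data

**Benchmark.** X has 100 i.i.d. N(0,1) columns plus 50 exact pairwise
sums (column 100+m = column 2m−1 + column 2m), giving rank 100 at
p = 150 — deliberate, severe collinearity. β is 0.9 on twelve listed
columns and 0.01 elsewhere; responses are drawn from each model with
σ² = 0.3, τ² = 0.45, φ = 0.21 (for the CAR kind, φ is validated against
the layout support at run time). All generators are pure functions of
(config, seed).

**Emulated trial.** 126 plots (2 P levels × 21 genotypes × 3 replicates,
P levels randomized to main-plot halves and genotypes within, per
replicate). Each plot's spectrum is a smooth canopy curve — NIR plateau,
green peak at 555 nm, red absorption at 670 nm — whose green/red features
shift with a per-plot nutrient status (genotype + fertilization + noise),
plus multiplicative measurement noise and edge-band missingness rising to
~90% at the sensor limits. ln(grain P) is linear in the true reflectance
at 550 and 670 nm plus a CAR field (τ² = 0.02, φ = 0.6) on the plot grid.
What this emulation does **not** contain: radiative-transfer canopy
physics, SWIR bands, weather/soil covariates, genotype × year structure,
or any guarantee that real wheat spectra share its noise spectrum — so
pipeline tests on it demonstrate the machinery end to end, not field
performance.

## Numerical choices and degenerate inputs

Tie-breaks in the most-probable-submodel summary go to the smaller model,
then lexicographic order. Constant predictors get unit scale during
standardization (their coefficients are then prior-dominated). Undefined
held-out correlations (constant index or prediction on a test set) are
flagged and excluded from means. Windows that empty a plot's spectrum,
extrapolation requests, isolated plots, φ outside its support, and
non-finite deviances all raise immediately with context rather than
propagating NaNs.

## Known limitations

Single-site γ updates can mix slowly under extreme collinearity (the
random permutation mitigates but does not remove this); φ in the CAR
model is only weakly identified at n = 126 with modest spatial signal, so
its posterior is broad even when τ² is well recovered; DIC focus differs
across model 2 vs models 1/3 as discussed; and the published real-data
tables cannot be reproduced here because the original spectra and plot
arrangement are not public — the package instead validates every formula
those tables rest on against oracles and the simulation benchmark.
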