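# phospec

Bayesian band selection and spatial regression for predicting **wheat
grain phosphorus** from hyperspectral canopy reflectance.

Determining grain phosphorus by wet chemistry is slow and expensive;
canopy spectroscopy is cheap and fast. `phospec` is for plant-phenotyping
and biostatistics researchers who want to (a) find which wavelengths carry
the phosphorus signal and (b) predict plot-level grain P while accounting
for the spatial correlation that field trials always carry.

## The models

For plot *i* with log grain-phosphorus concentration
*y<sub>i</sub>* = ln(grainP<sub>i</sub>) and resampled reflectance row
**x**<sub>i</sub> (101 bands on a 450–850 nm, 4 nm grid), three nested
views of the residual structure are fitted:

1. **Independent errors** — y<sub>i</sub> = **x**<sub>i</sub>ᵀβ + ε<sub>i</sub>,
   ε<sub>i</sub> ~ N(0, σ²).
2. **Geostatistical** — y<sub>i</sub> = **x**<sub>i</sub>ᵀβ + w<sub>i</sub> + ε<sub>i</sub>
   with latent field **w** ~ N(0, σ² H(φ)), H<sub>ij</sub>(φ) = exp(−φ‖s<sub>i</sub>−s<sub>j</sub>‖)
   on plot-centroid distances, and nugget ε<sub>i</sub> ~ N(0, τ²).
3. **CAR** — jointly **y** ~ N(Xβ, τ² (D<sub>M</sub> − φM)⁻¹), the
   conditionally autoregressive model on the rook-adjacency graph M of the
   plot grid (D<sub>M</sub> the row-sum diagonal; φ restricted to the
   eigenvalue interval that keeps the precision positive definite).

Every coefficient β<sub>j</sub> carries a **spike-and-slab prior**
(1−γ<sub>j</sub>)δ₀ + γ<sub>j</sub> N(μ<sub>j</sub>, ν<sub>j</sub>), so the
posterior inclusion probability PIP<sub>j</sub> = p(β<sub>j</sub> ≠ 0 | data)
performs wavelength selection during the fit. Variances get IG(0.01, 0.01)
priors; φ gets a uniform prior. Sampling is a Gibbs sweep
(γ/β jointly per coordinate, conjugate variance updates, latent-field
update) with a random-walk Metropolis step for φ on a logit scale. Models
are compared by DIC and by repeated-holdout cross-validation (25 of 126
plots, 5 repeats) with spatially aware prediction for held-out plots;
five classical vegetation indices (SR, NDVI, GNDVI, SAVI, OSAVI) serve as
baselines.

## Worked example

Simulate the selection benchmark (126 plots, 150 predictors with exact
pairwise-sum collinearity, twelve coefficients at 0.9 and the rest at
0.01, CAR responses with τ² = 0.45, φ = 0.21) and fit the CAR model:

```python
import phospec as pp

fs = pp.default_trial_layout()                       # 21 x 6 rook grid
cfg = pp.SimulationConfig(seed=1, model_kind="car")
X, beta, y = pp.simulate_dataset(cfg, fs)

res = pp.CARModel(y, X, field=fs).fit(
    n_iter=10_000, burn_in=5_000, thin=5, seed=2
)
print(res.summary())
```

```
CARModel (kind=car)
  n = 126, bands = 150, draws = 1000
  DIC = 151.71  (Dbar = 128.28, p_D = 23.43)
  phi MH acceptance = 0.33
  bands with PIP >= 0.6: 15 of 150
  most probable submodel: 15 bands (posterior frequency 0.114)
parameter       mean       sd       q2.5      q97.5   ess
intercept  -0.016157 0.057545  -0.131412   0.094701 919.0
 deviance 128.284240 7.945263 112.945328 145.055586 875.7
     tau2   0.546384 0.081626   0.413704   0.728952 865.2
      phi   0.524024 0.204965   0.080422   0.875833 523.9
```

The fit keeps 1000 thinned draws; the CAR variance τ² is recovered near
its generative value 0.45 (the 95% interval covers it), the positive φ
posterior reflects the simulated spatial dependence, and the fifteen
selected predictors are dominated by the twelve truly large coefficients
(`res.pip` gives the per-predictor probabilities; `res.selection_summary()`
the thresholded and most-probable submodels).

A fully self-contained field-trial analysis — emulated spectra with edge
missingness, preprocessing, all three models × three band-selection
criteria, DIC/correlation tables, vegetation-index comparison — runs from
the shell:

```bash
phospec run --emulate --reduced --seed 1 --outdir out/
```

which writes `dic_table.csv`, `cv_table.csv`, `index_table.csv` and
`summary.json` (stamped with the seed and a config hash), and prints the
CAR-vs-index gap in percentage points per year.

## Layout

```
src/phospec/
  preprocess.py   windowing, LSQ B-spline resampling, dataset assembly
  spatial.py      plot grids, adjacency, correlogram, CAR precision
  priors.py       spike-slab / variance / phi priors, MCMC config
  sampling.py     conjugate Gibbs updates + Metropolis step for phi
  models.py       IndependentModel, GeostatModel, CARModel (.fit())
  results.py      MCMCResults: summaries, DIC, prediction, persistence
  evaluation.py   selection summaries, DIC, CV splits, spatial prediction
  indices.py      SR / NDVI / GNDVI / SAVI / OSAVI baselines
  simulate.py     benchmark generator + emulated field trial
  pipeline.py     end-to-end orchestration and report tables
  cli.py          `phospec` command (simulate/prep/fit/indices/run)
docs/methods.md   modelling and design notes
```
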