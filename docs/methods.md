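# Methods

This note documents the statistical machinery in `droughtmort`: the models,
the numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Excess-mortality statistic

Each 0.5° cell's long-term mortality trend is a binomial GLM of the annual
mortality proportion (killed-canopy pixels / forest pixels) on calendar
year, fit per cell by IRLS (`statsmodels`).  The year covariate is centered
at the series midpoint purely for numerical conditioning; fitted rates are
unchanged.  Cells whose fit cannot be trusted — all-zero mortality, complete
separation, non-finite or extreme (|slope| > 5 per year) estimates — fall
back to a constant smoothed pooled rate `(Σ mortality + 0.5) / (Σ forest + 1)`
and are flagged, never dropped: the fractional deviation
`mort = (observed − fitted)/fitted` must stay defined everywhere.  `mort` is
scale-free in the pixel counts and bounded below by −1 (a year with zero
mortality).  The non-forest-ecoregion screen is taken as an input mask
(flag = majority of cell area non-forest); the ecoregion polygons themselves
are outside this package's scope.

## Climatic water balance

PET follows the classical Thornthwaite chain: annual heat index
I = Σ (T/5)^1.514 over months with T > 0; exponent
a = 6.75·10⁻⁷I³ − 7.71·10⁻⁵I² + 1.792·10⁻²I + 0.49239; unadjusted
PET = 16(10T/I)^a mm per 30-day month of 12-hour days, corrected by
(day length / 12)(days in month / 30); PET = 0 for T ≤ 0, and an all-freezing
year yields zero PET rather than an error.  Day length uses standard
solar-declination geometry at the cell-center latitude and mid-month day;
the sunset hour angle is clamped poleward of the polar circles (with a
warning), where Thornthwaite's calibration is dubious anyway.

CWB = precipitation − PET monthly.  Integration windows are backward-looking:
the window (m, w) averages the w months ending at observation month m, which
can reach into the previous calendar year (hence the generator emits a
spin-up year).  This is the only reading under which a March-to-July average
corresponds to observation month July with w = 5.  Z-scores are computed per
cell on the *windowed* series over all years, with the n−1 denominator; the
alternative order (z-score monthly, then window) is not offered because the
windowed z-score is what the response model consumes.  Zero-variance series
raise rather than emit NaNs.

## Response model and sampler

The hierarchical model, priors, and error family are described in the
README.  Points that were genuine design choices:

* **Mean-zero exGaussian error.**  The residual is
  ε = N(0, σ²_mort) + Exp(λ) − 1/λ.  Centering is not cosmetic: `mort` is a
  deviation from a fitted trend, so its population mean must be ≈ 0, and
  mean-parameterized exGaussian regression is also what the major applied
  implementations fit.  The `exgaussian_logpdf` primitive itself keeps the
  textbook parameterization (Gaussian-component mean μ, E[X] = μ + 1/λ);
  the model supplies μ = η − 1/λ.  A `scale = 1/λ` alias guards against the
  rate/scale ambiguity between implementations.
* **Stability.**  The log-density uses `erfcx` on the Gaussian-dominated
  flank and plain `log erfc` deep in the exponential tail, where the scaled
  form overflows.  Both branches are exercised by the heavy-tailed draws the
  model routinely produces.
* **Sampler.**  A blocked Gibbs sampler with the latent exponential
  component e_it ~ lower-truncated normal (inverse-CDF below a standardized
  bound of 5, shifted-exponential rejection beyond).  Conditional on e the
  model is linear-Gaussian: fixed effects + smooth weights update jointly,
  and each cell's (αᵢ, βᵢ) pair (likewise years) has a closed-form bivariate
  normal conditional, vectorized over groups.  Three mixing devices matter:
  (1) σ and λ move by *marginal-likelihood* Metropolis with e integrated
  out, removing the sticky coupling through the augmentation (valid because
  e is redrawn from its full conditional before its next use); (2) the λ
  proposal shifts α₀ by Δ(1/λ) so the Gaussian-component location is held
  fixed — a move along the posterior ridge; (3) after the effect updates an
  exact recentering (interweaving) step transfers the shared mean between
  (α₀, β₀) and each random-effect block.  Without (2)–(3) the intercept
  chain mixes an order of magnitude slower.  All Metropolis scales adapt
  during warm-up only (target acceptance 0.35).
* **Priors** (scaled by sd(y)): Normal(0, (2.5·sd)²) on α₀/β₀ — normal
  rather than Student-t to keep the location blocks conjugate;
  half-Student-t(3, 0, 2.5·sd) on every SD; Uniform(−1, 1) (LKJ(1)) on
  correlations; Exponential(mean sd(y)) on 1/λ.
* **Diagnostics.**  Rank-normalized split R-hat for every stored parameter
  (arviz).  Population/family-level parameters with R-hat > 1.05 raise (or
  warn, configurable); random-effect elements only warn.  Model comparison
  is PSIS-LOO on the pointwise exGaussian log-likelihood, with a warning
  when > 10% of points have Pareto k > 0.7.
* **Smooth term.**  Rank-k (default 10) low-rank thin-plate regression
  spline on the CWB z-score: eigen-truncation of the |r|³ kernel at the
  unique covariate values, null space {1, x} removed by constraint and by
  explicit centering against the separately modelled intercept/slope, and
  columns rescaled so the thin-plate penalty is the identity — making
  iid N(0, σ²_smooth) priors on γ exactly the roughness penalty.  The basis
  span was verified to coincide with the canonical low-rank construction
  (the frozen least-squares residual in the test suite pins it).

### Window selection

The month × window scan (March–August × 1–6) fits the *Gaussian* linear
mixed model by maximum likelihood for each of the 36 candidates and takes
the smallest AIC (9 parameters: 2 fixed + 7 (co)variance).  The marginal
likelihood is evaluated with the Woodbury identity — the random-effect
design has only q = 2·n_cells + 2·n_years columns, so each evaluation costs
one q × q Cholesky — and optimized by L-BFGS-B on log-SD / atanh-correlation
coordinates.  Singular fits refit with diagonal Σ and are flagged.  Ties
break to the earliest month, then the shortest window.  A hinge-only signal
with no linear component is nearly invisible to this Gaussian linear scan
(only the few percent of cell-years below the kink carry information); with
a realistic linear component the scan recovers the generating window
reliably.

### Probability curves and threshold

Each posterior draw contributes one simulated cell-year response curve: the
draw's population parameters plus one (αᵢ, βᵢ), one (αₜ, βₜ) sampled from
their population distributions and one residual — parameter *and* model
uncertainty.  P(excess > L | z) is the share of draws above level L on a
201-point grid over z ∈ [−3.5, 2.5].  The 95% ribbon splits the pooled
draws into 100 consecutive bins (80 draws each at the default 8,000) and
takes 2.5/97.5 percentiles of the per-bin curves.  The threshold is the
single breakpoint of each bin's level-0 curve — exhaustive search over all
splits with ≥ 15% of points per segment, two independent OLS lines, minimum
total RSS — summarized by the mean and central 95% interval over bins.
Exactly linear or flat curves yield no RSS improvement; such fits are
flagged and tie-break to the smallest admissible split rather than letting
rounding noise pick a winner.

### Hotspots and area accounting

A hotspot is a cell-year with `mort > 0` (strict) and CWB z below the
threshold.  Excess area is additive, `max(observed − fitted, 0) × rate ×
forest area` (0.09 ha per 30 m pixel), floored at zero so deficit years
cannot cancel drought-year excess; totals are produced at the central
threshold and both interval bounds, and monotonicity across thresholds is
asserted on every run.  Per-cell shares divide hotspot excess area by the
cell's total observed mortality area over the whole period; zero-mortality
cells get a missing share, not a zero or an exception.

## Synthetic-data generator

The generator is the inferential model run forwards, plus an observation
layer:

1. **Climate:** per cell, a seasonal mean cycle (July-peaking cosine) plus
   AR(1) monthly anomalies (default lag-1 autocorrelation 0.5), independent
   across cells; cell-level mean offsets and a latitude gradient create
   between-cell spread; precipitation is floored at 0; a full spin-up year
   precedes the first analysis year.
2. **Response:** crossed random effects from the configured Σᵢ, Σₜ;
   mean-zero exGaussian noise; linear or hinge response
   (`hinge_slope_below ≤ 0` left of the kink, flat above when β₀ = 0).
3. **Observation:** expected rate = trend_rate × (1 + mort), clipped to
   [0, 1] — the exact multiplicative inverse of the fractional-deviation
   statistic — then counts ~ Binomial(pixels_per_cell, rate) around
   per-cell logistic trends (logit intercept mean −5 ≈ 0.7%/yr, slope mean
   +0.02/yr, i.e. slowly rising background mortality).

Default response parameters are the published posterior means of the
pan-European fit (slope −1.88; spatial variances 0.18/0.03, correlation
0.03; temporal 0.08/0.04, correlation −0.08; σ²_mort 0.13; λ 0.53); the
default panel is 150 cells × 30 years from 1987 with 10,000 forest pixels
(900 ha) per cell — a deliberately reduced spatial domain (the continental
analysis has ~2,900 cells) that one CPU can refit in minutes.  A single
seed is split into named substreams (climate, effects, noise, binomial) via
`SeedSequence.spawn`, so identical (config, seed) pairs are bit-identical
and stages can be regenerated independently.

**What the generator does not emulate:** spatial correlation of climate and
effects between cells (available as independent draws only), disturbance
contagion, agent processes (fire, bark beetles, harvest), the 1–3-year lag
of beetle-induced mortality, and the commission/omission error of the
underlying mortality maps.  Passing recovery tests therefore demonstrate
that the *estimation machinery* is correct under the model's own
assumptions — not that the model is adequate for any particular real
landscape.

**Censoring on the observational route.**  With the default noise scale the
exponential tail is large (1/λ ≈ 1.9), so a substantial share of target
deviations fall below −1; the rate clips at 0 and the observed deviation
collapses onto the −1 boundary.  Equation-level panels
(`model_frame("truth")`, `response_source="truth"`) reproduce the response
model exactly and are what the recovery experiments use; count-derived
panels (`"panel"`) additionally carry this censoring plus binomial noise
and trend-estimation error, which attenuates refit slopes and distorts the
error-family parameters.  This is a property of the generative design, not
a sampler defect, and mirrors the fact that fractional-deviation data are
bounded below by construction while the exGaussian likelihood is not.

## Problem sizes used in the shipped experiments

Recovery runs use 150 cells × 30 years with 4 chains × 2,000 iterations
(1,000 warm-up); threshold recovery uses 200 cells with 4 × 1,500 (750);
the draw-bookkeeping check runs the full 4 × 4,000 (2,000) schedule on a
small panel.  These sizes give posterior standard deviations a few percent
of the parameter values — tight enough to make the recovery checks
meaningful — while a complete test run stays in the minutes range.

## File formats

Panels and results are long-format CSV (cell_id, year[, month], value
columns) plus JSON for configuration/truth/manifest records; posteriors are
persisted as `.npz` containers holding the draw arrays, the model spec and
the spline basis.  Raster/NetCDF export is intentionally out of scope here;
the CSV tables carry cell centers so users can rasterize with their GIS
stack of choice.
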