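# droughtmort

Tools for asking, at continental scale, whether forests die more when water
runs short — and where the drought threshold lies.

The package implements a complete analysis pipeline linking gridded annual
**forest canopy mortality** (satellite-derived counts of killed-canopy pixels
per 0.5° cell and year) to **drought**, measured as the climatic water
balance (CWB = monthly precipitation − Thornthwaite potential
evapotranspiration), plus a synthetic-data generator with recorded ground
truth so the whole chain can be validated by parameter recovery.  It is
aimed at forest-disturbance and climate-impact researchers who want a
reusable, tested version of this analysis rather than a one-off script pile.

## The model

Excess mortality in cell *i* and year *t* is the fractional deviation from
the cell's long-term trend (a per-cell binomial-logit regression of the
mortality rate on year):

    mort_it = (observed_rate − fitted_rate) / fitted_rate

so 0 is "on trend", +1 is a doubling of the annual mortality area, −1 a total
mortality deficit.  The drought response is a hierarchical model with crossed
cell and year random effects:

    mort_it = (α₀ + αᵢ + αₜ) + (β₀ + βᵢ + βₜ)·z_it + f(z_it) + ε_it

    (αᵢ, βᵢ) ~ MVN(0, Σᵢ)        (αₜ, βₜ) ~ MVN(0, Σₜ)
    f(z) = Σⱼ Bⱼ(z)·γⱼ,   γⱼ ~ N(0, σ²_smooth),  k = 10 thin-plate basis
    ε_it ~ exGaussian(σ²_mort, λ), centered to mean zero

where `z_it` is the per-cell z-score of CWB averaged over an integration
window (the window — observation month × 1–6 months — is chosen by an AIC
scan of Gaussian maximum-likelihood fits; the Bayesian refit uses the
right-skewed exGaussian error family, i.e. Gaussian + Exponential(rate λ)).
Posterior draws are turned into probability-of-excess curves over CWB, the
drought **threshold** is the single breakpoint of the P(excess > 0) curve
(two-segment least squares per draw-bin), and cell-years where excess
mortality co-occurs with CWB below the threshold are accumulated into
hotspot maps and drought-attributable area totals.

Inference is a blocked Gibbs sampler written for exactly this model (latent
exponential augmentation makes every location parameter conjugate;
variance/correlation parameters move by adaptive Metropolis), with
rank-normalized split R-hat and PSIS-LOO model comparison via `arviz`.

## Worked example

Simulate a 120-cell × 25-year panel whose mortality is driven by the
March–July CWB through a hinge response (flat above a kink at −1.6 z-units,
slope −1.5 below it), then run the full pipeline on it:

```python
import droughtmort as dm

cfg = dm.PipelineConfig(
    truth={"n_cells": 120, "n_years": 25, "response_shape": "hinge",
           "beta0": 0.0, "hinge_location": -1.6, "hinge_slope_below": -1.5},
    chains=4, iterations=1500, warmup=750,
    select_window=False, month=7, window=5,   # March-July integration
    response_source="truth", seed=42)
manifest = dm.run_pipeline(cfg, "out/")
```

The run report (`out/report.md`) ends with

```
## Drought threshold

Breakpoint of P(excess > 0): -1.59 z-units (95% interval -2.14 to -0.90).

## Drought-attributable excess mortality

Total excess area by threshold (ha): {'-2.14': 323.2, '-1.59': 781.4, '-0.90': 2062.1}
```

The detected threshold (−1.59) recovers the generator's kink (−1.6): once
the integrated water balance falls ~1.6 local standard deviations below
normal, the probability of excess canopy mortality rises steeply.  The area
totals count mortality above trend in drought cell-years, at the central
threshold and its interval bounds (stricter threshold ⇒ fewer drought
cell-years ⇒ smaller total).  The report also contains the posterior summary
table with R-hat per parameter and, for synthetic runs, a truth-vs-posterior
recovery table.

Every stage is also exposed on its own (`generate_dataset`,
`deviation_panel`, `cwb_z_panel`, `select_window`, `fit_bayes`,
`detect_threshold`, `map_hotspots`, …) and through the `droughtmort` CLI
(`simulate`, `trend`, `climate`, `fit`, `threshold`, `hotspots`, `run`).

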