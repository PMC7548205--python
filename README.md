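# nicheshift

Presence-background species distribution modelling with climate-scenario
projection and range-shift accounting — built for studies like the
climate-change assessment of the five widespread southeastern US palms
(*Rhapidophyllum hystrix*, *Sabal etonia*, *S. minor*, *S. palmetto*,
*Serenoa repens*), and tested end-to-end on synthetic landscapes with
known truth.

## What it does

Given occurrence records and a stack of aligned environmental rasters
(bioclimatic, soil, elevation layers), the pipeline:

1. **cleans and thins** occurrences to one record per grid cell;
2. fits a **maximum-entropy niche model**: the suitability density over
   background cells is q(x) = exp(λ·f(x))/Z with features f (linear,
   quadratic, product, hinge expansions scaled to [0,1]), estimated by
   maximizing the penalized presence log-likelihood
   `mean_presence log q(x) − Σⱼ βⱼ|λⱼ|`, where
   `βⱼ = β · base(class, m) · sⱼ/√m` and β is the user-facing
   regularization multiplier;
3. **screens variables** by isolated training gain and pairwise
   Pearson |r| (default cutoff 0.8), then searches **all variable
   subsets × a β grid** ({0.5, 1, 2, 3, 4}), scoring each candidate by
   small-sample-corrected AIC —
   `AICc = 2k − 2 lnL + 2k(k+1)/(n−k−1)` with lnL standardized over the
   landscape and k = nonzero coefficients — plus Akaike weights,
   held-out (70/30) AUC and 10-fold cross-validated AUC;
4. **projects** the selected model onto per-GCM future climate stacks
   and averages them (unweighted, on the probability scale) into one
   ensemble map per RCP × horizon scenario;
5. **bands** suitability maps into five classes (>0.50 = highly
   suitable) and reports range areas (spherical km²), % change, area
   common to the current range, % retained, and the suitability-weighted
   centroid's geodesic shift, compass direction and km/decade rate.

A synthetic-data module generates autocorrelated, cross-correlated
environmental fields, virtual species with known response curves,
presence samples, and shifted/noised "GCM" future stacks, so every stage
is testable without downloading real rasters.

## Worked example

```python
import numpy as np
from nicheshift import (SyntheticWorldConfig, SyntheticSpecies,
                        generate_landscape, true_suitability, sample_presences,
                        make_future, thin_to_grid, sample_background,
                        project_scenario, classify_bands, compare_ranges)
from nicheshift.pipeline import PipelineConfig, run

world = generate_landscape(SyntheticWorldConfig(n_rows=100, n_cols=100, seed=8))
species = SyntheticSpecies(n_presence=250)          # narrow thermal optimum
truth = true_suitability(species, world)
occ = sample_presences(truth, 250, seed=9)
gcms = make_future(world, deltas={"BIO11": 3.0, "BIO8": 3.0}, n_gcms=5,
                   gcm_noise_sd=0.3, seed=10, scenario_tag="2070_RCP8.5")
result = run(world, occ, {"2070_RCP8.5": (2070, {g.scenario_tag: g for g in gcms})},
             PipelineConfig.from_dict({
                 "background_n": 2000, "subset_sizes": (2, 3),
                 "feature_classes": ("linear", "quadratic"),
                 "seeds": {"background": 1, "thinning": 2, "cv": 3}}))
print(result.best.variables, result.best.beta, round(result.best.auc_cv_mean, 3))
print(result.range_table[["scenario", "pct_change", "pct_retained",
                          "shift_km", "compass"]].to_string(index=False))
```

prints (numbers from this exact run):

```
('BIO8', 'BIO11', 'BIO18') 0.5 0.928
   scenario  pct_change  pct_retained  shift_km compass
2070_RCP8.5      213.34         68.07        22       S
```

The selected variable set is exactly the species' three true variables,
and the 10-fold CV AUC (0.93) reflects a narrow-niche species. This
virtual species is a climate-change winner: its cold-quarter optimum
(12 °C) sits above the landscape mean (8 °C), so +3 °C expands the
highly suitable (>0.50) area about threefold, while only 68% of the
*current* footprint stays highly suitable and the range centroid moves
22 km.

The same stages are scriptable from the shell:

```sh
nicheshift simulate --out fixture/ --seed 5 --rows 100 --cols 100
nicheshift run --config config.json
nicheshift metrics --current now.asc --future 2070.asc --year 2070
```

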