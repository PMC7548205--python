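# Methods

## Model

The core estimator is a presence-background maximum-entropy density.
Let B be a uniform sample (without replacement) of non-nodata cells —
the background — and f(x) ∈ [0,1]^J a feature expansion of the
environmental values at a cell. The model is

    q(x) = exp(λ·f(x)) / Z,   Z = Σ_{b∈B} exp(λ·f(b)),

so raw scores sum to one over the background sample (presences are not
added to the partition set). λ maximizes

    (1/m) Σ_{presences} log q(x_i) − Σ_j β_j |λ_j|,

with per-feature penalties β_j = β · base(class, m) · s_j/√m: m is the
presence count, s_j the feature's standard deviation over presences
(floored at 1e-4 so features constant across presences stay weakly
penalized), and base(class, m) the conventional class schedule —
linear/quadratic/product interpolated on sample size through
(0→1.0, 10→1.0, 30→0.2, 100→0.05), hinge 0.5, threshold 1.0. β is the
single user-facing regularization multiplier; β → ∞ recovers the
uniform model.

At an optimum the KKT conditions give |E_q[f_j] − mean_pres f_j| ≤ β_j,
with equality where λ_j ≠ 0. The optimizer is L-BFGS-B on the split
λ = u − v (u, v ≥ 0), which makes the problem smooth and
box-constrained. Two presets are exposed: `high` (ftol 1e-12,
gtol 1e-8, 5000 iterations; meets the KKT gap to ~1e-4 and is the
default for any fit a user asks for directly) and `search` (150
iterations, single-precision matrices; used inside the candidate
search, where the AICc *ranking*, not the last digit of the optimum,
matters). Non-convergence is always reported in the fit report, never
silent. The fitted report also carries the training gain
(mean presence log q + ln N_background) and the entropy H of q.

### Features

Linear and quadratic terms per variable, products per unordered pair,
and forward/reverse hinges at (by default) 50 background-quantile knots.
Every feature is affinely rescaled to [0,1] using its background range;
knots lie strictly inside each variable's training range; constant
features are dropped with a warning. With clamping on (the default for
projection), inputs are truncated to the training range before feature
evaluation, which bounds extrapolation.

### Output transforms

raw (q itself, using the training Z), cumulative (percentile of raw
among background), logistic τe^H q/(1+τe^H q) with τ = 0.5, and cloglog
1 − exp(−e^H q). The default display scale is cloglog; the choice of
scale the suitability bands operate on is explicit configuration, since
both conventions exist in the literature.

## Model selection

Variables are first ranked by isolated gain (a single-variable fit) and
screened for collinearity: pairs with Pearson |r| ≥ 0.8 on the
background sample are resolved greedily, highest |r| first, dropping
the lower-gain member. The search space is every subset of size 2–6 of
the screened variables crossed with β ∈ {0.5, 1, 2, 3, 4}. For each
candidate:

- AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), where k counts nonzero λ after
  fitting and lnL standardizes raw scores to sum to one over **all**
  non-nodata cells of the study region (not just the background
  sample) — the convention that makes presence-only likelihoods
  comparable across models. Candidates with n ≤ k+1 are excluded and
  logged.
- Akaike weights are normalized over all valid candidates.
- Discrimination: a 70/30 presence split (test AUC) and 10-fold CV
  (folds partition presences; the background is shared). AUC is the
  rank (Mann-Whitney) statistic with ties counted ½. To keep the full
  search affordable these two statistics are computed only for models
  within ΔAICc ≤ 4 of the best (mirroring reports that print AUC for
  top models only); `evaluate_candidate` computes them for any
  candidate on request.

Ties in AICc break by smaller k, then smaller β, then variable names.
Successive β values on the same subset are warm-started from the
previous solution; this changes nothing about the stated convergence
contract, only the iteration count.

## Projection and range metrics

A scenario (RCP × horizon) is a set of per-GCM layer stacks; soil and
elevation layers are identical across members. The model is evaluated
per GCM on the probability scale and averaged cellwise without weights;
averaging after the transform is the documented choice (the ensemble of
"maps", not of raw densities). Suitability is banded into
(0,0.10], (0.10,0.20], (0.20,0.35], (0.35,0.50], (0.50,1]; exactly 0.50
falls in band 4, so band 5 is strictly ">50%".

Areas are true spherical cell areas, A = R²·Δλ·(sin φ_top − sin φ_bot)
with R = 6371.0088 km, summed over band-5 cells; a constant
nominal-area mode (default 25 km²/cell) exists for sensitivity checks.
Range change between a current and a future banded map reports % change
of band-5 area, the area common to both, and % of the current range
retained. Centroids are, by default, suitability × cell-area weighted
means of cell-center coordinates over all cells (a band-5-only
area-weighted mode is available); shifts use the haversine distance and
initial bearing on the same sphere, a 16-wind compass label, and a
km/decade rate with baseline year 2010 (so 4 decades to 2050 and 6 to
2070). Percentages are rounded to 2 decimals and rates to integers in
reports only; full precision is kept internally. Medians use the
midpoint convention (mean of the two central order statistics).

Two documented inconsistencies in the published palm tables are flagged
rather than reproduced: the *S. minor* "% change" column equals
−(100 − % retained) instead of (future−current)/current, and a handful
of printed per-decade rates disagree with distance/decades (e.g. 63 km
over 4 decades printed as 21). The package always recomputes
percentages from areas and rates from distances, and carries the
published rate column alongside for summaries that pool it.

## Synthetic data

Environmental layers are Gaussian random fields: white noise smoothed
with a Gaussian kernel (autocorrelation length 15 cells by default),
whitened against the realization's empirical correlation, mixed through
a matrix factor of the target cross-correlation (so realized pairwise r
matches the target even on small grids, where chance correlations
between smooth fields are otherwise large), and rescaled to plausible
per-layer means/sds (temperatures in °C, precipitation in mm). The
default world is 200×200 cells of 2.5 arc-minutes with six climate-like
and two static soil layers.

A virtual species' true occurrence probability is a product of
per-variable responses — Gaussian optima and logistic ramps —
max-normalized to 1. The default species responds to three layers with
a narrow thermal optimum and a precipitation ramp, giving fitted-model
AUCs near 0.95, matching the discrimination typical of real
narrow-range species against a wide study extent. Presences are drawn
with probability proportional to truth × cell area (with replacement;
duplicates are later removed by thinning), placed at cell centers with
sub-cell jitter. Future "GCM" stacks add per-layer shifts plus smooth
GCM-specific noise to climate layers only.

What the generator does **not** emulate: real covariance structure
between bioclimatic variables (they are independent by default),
latitudinal climate gradients, observation bias, and coastline-shaped
nodata masks. Passing tests therefore demonstrate the estimator and
bookkeeping are correct under known truth, not that any real species'
map is right.

### Recovery experiment

Each replicate simulates a 200×200 world with six candidate layers
(three of them the species' true variables), samples 200 presences,
thins, and runs the subset (sizes 2–4) × β-grid search with linear +
quadratic features (the truth's log-response is quadratic, so the
family is well-specified) over a background of 1,000 cells; CV AUC is
computed for the winner. The report gives the fraction of replicates
whose selected variable set equals the truth, the winners' CV AUC, and
how often fitted response-curve optima fall within one curve-grid step
of the true optimum. The optimum estimator is consistent — errors
shrink with presence count — but at n of a few hundred single
replicates can miss by 1-2 curve steps, so the corresponding test
asserts the median across replicates.

## Numerical choices and limitations

- Grids are WGS84 decimal degrees, edge-registered, row 0 northernmost,
  half-open cell intervals; points on shared edges belong to the cell
  east/south. Geometry mismatches between layers are errors — nothing
  is resampled silently.
- Problem sizes in the test suite (100×100 worlds, 1,000-2,000
  background cells for unit-level checks; the full 200×200 / 10,000
  background / 11-GCM configuration in one end-to-end test) were chosen
  as the smallest sizes at which the statistical contracts are sharp.
- The cumulative output of `predict` uses the projected stack's own raw
  scores as the percentile reference, since the per-cell training
  background is not stored in the serialized model.
- Exact coordinate duplicates are detected after rounding to 6
  decimals (~0.1 m); no coordinate-uncertainty filtering is attempted.
- The "native range" clip is caller-supplied (bounding box or polygon);
  the package ships no range polygons.
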