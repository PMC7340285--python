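# Methods

This note documents the statistical machinery in `whalekrill`, the
assumptions behind each stage, the defaults and why they were chosen,
and the places where a design decision had to be made because the
field-standard procedure is ambiguous.

## Study system and the synthetic generator

The package models a multi-year (14-year analog, 2004–2017; May, June,
July and September cruises) line-transect survey of a small coastal
upwelling region. All geometry is planar, in km, on a 1-km² grid: at the
scale of a single study area (~30 km across) projection distortion is
negligible and "distance to feature" is plain Euclidean distance to a
synthetic coastline, island, bank and 200-m isobath. Depth follows a
shelf/slope profile crossing 200 m at the isobath with a shoal at the
bank; the contour index is the within-neighbourhood relief
(max − min)/max scaled to 0–100.

`synthetic.simulate_observations` draws data from exactly the families
the analysis fits, so parameter recovery is a meaningful test:

- **Oceanographic fields**: stationary isotropic Gaussian random fields
  with exponential covariance C(h) = (sill − nugget)·exp(−h/range) per
  variable and cruise. Default means, sills and ranges are set so the
  simulated values sit inside the observed ranges of the real variables
  (e.g. surface temperature ~12.6 ± 1.4 °C, range 8 km). The range is an
  e-folding length, not a "practical range".
- **Climate indices** (SOI, PDO, NPGO, UI): stationary AR(1) monthly
  series; AR coefficients 0.5–0.8 and innovation SDs chosen so marginal
  mean/SD match the published monthly summaries (UI has mean 191 and
  marginal SD ≈ 81). Each cruise carries the index at lags 0–3 months.
- **Transects and bins**: east–west lines at 3-km spacing cut into 3-km
  bins; the final segment of each line is randomly truncated and
  discarded when shorter than 1 km (the survey's end-of-line rule).
  Survey area is 2 · length · ESW with ESW and g(0) looked up from
  simulated sea-state/visibility classes (detection-function fitting is
  out of scope; conditions map to supplied values).
- **Krill**: hurdle — presence ~ Bernoulli(logit⁻¹(Xγ)); positive
  biomass ~ zero-truncated NB2 with mean exp(Xβ + log volume) and
  dispersion θ = 1.5, emitted as integer grams (the krill model is a
  count regression; the study reports biomass totals as integers).
  The acoustic volume offset is cell count × a constant 3000 m³ cell.
- **Whales**: counts ~ NB2(exp(Xβ + log area), θ). Default intercepts
  put blue whale presence near 3% of bins and humpback presence near
  16–22%, matching the survey's sparsity regime.

The default truth uses the smallest covariate basis that exercises every
selection pathway — one centered-quadratic oceanographic term, one
distance term, one lagged climate term per species. What the generator
does **not** emulate: weather-driven effort gaps, ship-track logistics,
anisotropy, temporal autocorrelation of fields between cruises, and
real coastline geometry. Tests passing on this generator therefore
demonstrate correctness of the estimators under their stated
assumptions, not robustness to every failure mode of field data.

## Kriging and the QC gates

Each (cruise, variable, layer) surface is interpolated by global
ordinary kriging (all points in the neighbourhood; synthetic cruises
have at most a few hundred measurements) under isotropy. The
semivariogram convention is total sill with
γ(h) = nugget + (sill − nugget)·g(h/range); candidate families are
exponential, spherical (unit scale reached at 3× the range parameter so
families are comparable) and gaussian. Fitting is weighted least squares
on the binned empirical semivariogram (weights √pair-count); when the
measurement points are available, the family is chosen by leave-one-out
RMSE of the induced kriging predictor, which is the "minimize prediction
mean square error" reading of parameter optimization. Fits whose rise
across the observed lags is below 1% of the empirical maximum are
degenerate — that includes both huge-range and sub-lag-range "fits" —
and fall back to pure nugget with a warning. Duplicate locations are
averaged before solving, which deterministically avoids singular
systems.

A surface is accepted when all four LOOCV gates hold: >90% of held-out
predictions within the measured mean ± 1.96 SD; >90% within ± 2 SD;
%RMSE < 30; |%ME| < 2. Two readings had to be fixed here:

- **Denominators.** %RMSE and %ME are normalized by the range
  (max − min) of the measured values; the thresholds are published
  without a denominator and range-normalization is the common convention
  that makes them scale-free.
- **"Within the 95% CI of the measured data"** is read as a tolerance
  interval (mean ± 1.96 SD), not a CI on the mean — the latter shrinks
  with √n and would be failed by nearly any interpolator.

On failure the surface is de-trended with a full second-order polynomial
in (x, y) by least squares, the residuals are re-kriged, and QC is
re-evaluated with an honest LOOCV (trend refit without the held-out
point). One detrending pass is applied; a surface still failing is
emitted flagged `passed=False` with a prominent warning rather than
iterated, since no iteration rule is defined. In practice the gate that
fires on sparse, strongly trended data is the |%ME| < 2 bias gate;
global kriging interpolates smooth trends too well for the %RMSE gate to
trigger.

## Acoustic biomass

Biomass density is B = s_A / Σ f_l σ_bs,l · Σ f_l M(L_l): linear in
backscatter and invariant to splitting length classes. The packaged
cross-section table is synthetic — σ_bs ∝ L² anchored at 10⁻⁶ m² for a
20-mm animal — because the physics-based target-strength model is
upstream of this package; any positive monotone table exercises the same
arithmetic, and callers supply their own. Note the printed length–weight
quadratic has a negative discriminant, so mass is positive at every
length (minimum 0.0014 g at 4.25 mm); the non-positivity guard can only
fire for user-modified coefficients.

## GLM engine

All count families are NB2 (variance μ + μ²/θ); θ is reported, and AIC =
2k − 2ℓ / BIC = k·log n − 2ℓ count every estimated parameter including
θ and zero-inflation coefficients. The hurdle's two parts are estimated
independently (the likelihood factorizes); combined criteria use the
summed log-likelihood, total parameter count and the full n. The effort
offset enters the count part only — effort scales measured biomass, and
the published model description attaches its single offset to the
abundance process, not presence.

Numerical choices that matter:

- **Column standardization.** Every design is fit on z-scored columns
  (raw-scale polynomial columns such as salinity³ ≈ 4·10⁴ condition the
  Hessian catastrophically) and coefficients, standard errors and Wald
  p-values are mapped back to the natural scale through the exact affine
  transformation of the parameter covariance.
- **Start values.** NB-family fits start from a Poisson fit plus a
  method-of-moments dispersion estimate, then BFGS with a Nelder-Mead
  restart on non-convergence; convergence is always flagged, never
  silently accepted.
- **Transforms.** The distance-ladder transforms are log(x) = ln(1 + x)
  and invlog(x) = 1/(1 + ln(1 + x)); both are defined at zero distance
  (bins sitting on a feature) and the inverse-log is a bounded,
  decreasing alternative shape, which is the role it plays in the
  screening ladder.
- **Vuong test.** z = √n · mean(mᵢ)/sd(mᵢ) on per-observation
  log-likelihood differences; a zero-inflated model is adopted only on
  significant improvement (p < 0.05), otherwise "neither".
- **Moran's I** uses inverse-distance or fixed-band weights with the
  normality-based variance; **Nagelkerke R²** is computed from the null
  and fitted log-likelihoods directly.
- **k-fold CV** (k = 10, 20 runs by default) derives fold assignments
  from seed + run index, so reports are bit-reproducible; a fold whose
  training complement loses a response class is skipped with a warning.

## Covariate selection

Per model part: polynomial covariates enter at the highest order whose
top coefficient is significant in a univariate fit (p < 0.05); distance
covariates at the most significant of four transforms (block LRT against
the null, comparable across 1- and 2-column candidates); climate indices
at the most significant lag 0–3 (quadratic form by default, since the
final krill models use quadratic climate terms). Backward elimination
enforces marginality (a polynomial sheds its top order first) and
prefers drops that decrease AIC, trying candidates in order of
decreasing p. A hard "AIC must decrease" stop would routinely strand the
last noise term — it is the maximum of several χ² statistics, so its
single-step LRT exceeds 2 in roughly 40% of replicates — therefore
elimination continues to full significance, steps where AIC rose are
recorded in `StepwisePath.aic_conflicts`, and the ΔAIC-2 / lowest-BIC
rule over all path models adjudicates; with a within-2-AIC tie the BIC
tie-break virtually always selects the fully pruned model. Under this
protocol the true term set (quadratic + linear truth, three noise
covariates, n = 3000) is recovered exactly in ≥80% of replicates, with
the shortfall from 100% being the expected α-level noise retention.
Ties in the least-significant choice break lexicographically by column
name for determinism. Year interactions are tested afterwards, one LRT
per retained static covariate (year as a categorical factor on the
linear column), kept at p < 0.05 with an AIC improvement.

## Maps, hotspots, overlap

Grid predictions fix the offset at log 1 — maps are per-unit-effort
expected abundance, and the decile scaling used for display is
offset-invariant. Decile classes pool all maps of a species × scheme set
(boundary ties take the lower class). The overall map is a two-stage
mean — months within year, then across years — which equals the pooled
mean only when every year contributes the same number of months; the
two-stage form weights years equally under uneven sampling.

Gi* uses binary fixed-band weights of 3 km with self-inclusion (the bin
scale; the original weight scheme is unreported) and the global-mean/SD
form of the statistic; constant rasters get z ≡ 0 with a flag. p-values
are BH-adjusted within each monthly raster, the hotspot mask keeps
positive-z cells with adjusted p < 0.05, masked z-scores are rescaled to
[0, 1] over the masked cells only (a single masked cell maps to 1 — the
rescaling is only well-defined on retained cells), and the persistence
surface is the cellwise sum over months (range 0..M). On finite rasters
the z-scores do not sum to zero — neighbourhood weight totals vary at
edges — so correctness is anchored instead by exact equivalence to a
brute-force evaluation of the formula and by null calibration (empty FDR
masks on ≥90% of i.i.d. rasters).

The AB ratio is the spatial covariance of predator and prey fields over
the product of their means; the local decomposition averages back to the
global value exactly (an identity the tests check at 10⁻¹²), temporal
SD uses the n−1 denominator, and per-year global values are computed on
annual-averaged maps.

## Pipeline scale defaults

The pipeline's synthetic default (8 cruises on a 30×30 km grid) and the
test/acceptance configurations (4–8 cruises, 18–24 km extents, 150-point
kriging replicates, n = 3000–5000 regression recoveries) are sized so a
complete run of the suite and the acceptance script each finish in a few
minutes on one CPU while keeping every Monte-Carlo assertion at its
stated replicate count. The study-scale run (41 cruises → 246 surfaces)
is bookkeeping-checked directly and available through the CLI config.

## Known limitations

- One detrending pass; no universal kriging, anisotropy or co-kriging.
- The hurdle offset is not applied to the presence part (configurable
  upstream question; the count-only choice is documented above).
- Selection p-values are conditional on the screened design; no
  selective-inference correction is attempted (matching the original
  protocol).
- The Gi* p-values use the normal approximation, which is what the FDR
  masking consumes; no permutation alternative is provided.
- The synthetic calendar assigns survey months cyclically; it does not
  reproduce the real program's uneven month-by-year sampling pattern
  beyond supporting it structurally.
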