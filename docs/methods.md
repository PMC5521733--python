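# Methods

## The valuation model and its estimation

The core statistical object is a linear mixed model for the natural log of
a per-hectare, per-year ecosystem-service (ES) value, with fixed effects
for study descriptors and spatial covariates and a random intercept per
country capturing institutional and socio-political factors shared within
a country. Two clustered factors — ES class (cultural / provisioning /
regulating) and valuation method (cost-based / revealed / stated
preference) — enter as treatment-coded dummies against the cultural and
cost-based baselines; continuous predictors are z-scored against the
training sample, so coefficients are per-SD effects and the stored training
moments travel with the fitted model for prediction.

Estimation is full maximum likelihood, not REML, because the model-set
machinery compares likelihoods across different fixed-effect sets. For the
single-random-intercept family the ML problem profiles to one dimension:
given the variance ratio ρ = σ₁²/σ², GLS equals OLS on quasi-demeaned data
(each observation shrunk toward its country mean by
θ_c = 1 − 1/√(1 + n_c ρ)), σ² is profiled in closed form, and the profile
log-likelihood is maximized over log ρ by bounded scalar search with the
ρ = 0 boundary always evaluated. A fit whose optimum sits at the boundary
is reported with `sigma_country = 0` and a `singular` flag; a one-country
dataset degenerates to fixed-effects regression the same way. The fitter
is validated in the test suite against an independent library
implementation of the same likelihood (exact agreement in log-likelihood,
coefficients and variance components); a single fit costs ~1 ms, which is
what makes full enumeration, leave-one-out replay and bootstrap refitting
affordable. Wald covariance of the fixed effects is conditional on the
estimated variance ratio; measured 95% CI coverage at n = 500 is 0.92–0.98
per coefficient.

Model selection enumerates all 2^J subsets of the candidate terms
(default J = 8, hence 256 models, intercept-only included), ranks them by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = fixed effects + 2 variance
parameters, and retains the set within 2 AICc units of the best (boundary
inclusive). Akaike weights are computed over the full enumeration and
renormalized over the retained set. Coefficients are conditionally
averaged (over the models containing each term); predictions are averaged
at the prediction level with the same weights, which is equivalent for
linear predictors.

## Prediction and TEV mapping

Spatial prediction builds the per-cell covariate table from the grid, makes
one log-scale prediction per valuation-method level, averages the three
levels on the log scale, and back-transforms by plain exponentiation
(no smearing correction by default; the predicted value is the conditional
median of the lognormal, a deliberate, documented choice). Conditional
prediction adds the BLUP country intercept where the country was observed;
unseen countries use the fixed-effects part only. Publication year and
forest area have no spatial counterpart and enter at their training means
(standardized zero) when absent; peer-review status, which likewise has no
map, is fixed at 1 — predictions are for peer-reviewed-grade values. ES
classes are combined into a per-cell total ES value with multipliers
(5, 6, 5): five provisioning, seven-minus-one regulating (the carbon-
overlapping service is excluded to avoid double counting), five cultural;
all three are configurable.

## Cross-validation and baselines

Leave-one-out CV replays the *entire* procedure — enumeration, selection,
averaging — on each fold. Accuracy is summarized by MAPE on the log-value
scale (the model's response; a back-transformed MAPE is also reported) and
by the predicted-versus-observed regression forced through the origin with
observed regressed on predicted (slope = Σpred·obs/Σpred²), so slopes
below 1 indicate over-dispersed predictions. The direct-benefit-transfer
baselines predict a held-out record by the leave-one-out mean log value of
its ES class (global) or ES class × region (regional), with a global-mean
fallback for empty strata.

## Uncertainty propagation

The bootstrap resamples records (rows) with replacement B times (a
study-level cluster bootstrap is available), refits the already-selected
model structures, recomputes their weights, and re-predicts the TEV
surface; full re-enumeration per replicate sits behind a flag. The
covariate standardization and mean-fill values are *fixed preprocessing*
from the original fit: replicates re-estimate coefficients on an identical
design scale, so a zero-noise dataset yields a degenerate ensemble, as it
should. A replicate whose resample produces a rank-deficient design (a
factor level vanishing) is redrawn and counted. Note that the ensemble
mean of the back-transformed maps is *not* an unbiased estimate of the
point map — exp() is convex, so the ensemble mean sits a few percent above
it with a bias that does not vanish as B grows; the consistency test
therefore uses a 10% relative band rather than a Monte Carlo
standard-error band.

The Monte Carlo engine draws, per replicate: one of the B bootstrap TEV
maps; a perturbed loss map (loss cells retained with p = 0.87, no-loss
cells flipped with p = 0.003 and assigned their country's mean loss area);
a market carbon price uniformly from the daily series; a social carbon
price uniformly from the damage-draw pool; each crop-country price from
Normal(mean, sd) truncated at zero; and, for scenarios A/B, a fresh crop
assignment. One master seed spawns an independent stream per
(source, replicate) via spawn keys, so disabling any source leaves every
other draw unchanged — the ablation tests rely on this contract.
Replicates reduce to empirical percentiles (numpy's linear-interpolation
quantile definition) per cell and per aggregate. The shipped defaults are
B = 500 and M = 200; the test suite and acceptance script use smaller
ensembles (B = 8–100, M = 5–200 depending on the property under test) and
state them per test.

## Economic components

Carbon: emissions per hectare are (aboveground + belowground + dead
organic matter + peat) carbon × 44/12, with mineral soil carbon
conservatively held constant. Peat contributes depth × 500 tC/ha/m by
default — peat depth maps carry no density, so the per-metre density is an
explicit free parameter. The peat stock is treated as a one-off emission
at conversion and annualized, an interpretation flagged here because
ongoing oxidation is a defensible alternative. Prices default to the
per-tCO₂e basis with reference values 13.6 (market) and mean 30 (social)
per tonne; a per-tC basis (scaling by 12/44) is a config switch because
price quotations in the literature mix the two conventions. One-off values
annualize at 5% over 100 years.

Rents: AR = y·p − c per deforested cell. Scenario A/B assignment draws
from the country's area-weighted crop composition (cattle included via
pasture); C/D take the argmax of *net* potential rent (potential yields,
full costs) with ties broken by fixed crop order — so C and D share an
assignment and D ≥ C cell-wise, exactly. Costs: labour = person-days ×
daily wage (agricultural, falling back to manufacturing); fertilizer =
usage × national price; transport (C/D cash crops only) = per-tonne truck
cost × yield, with an 18 m³ truck at 45 km/h, 0.3 L/km, one driver, empty
return, and a default load density of 1 t/m³ (capacity is volumetric,
yields are in tonnes; the conversion is a stated assumption). A missing
crop-country price falls back to a configured donor country, then to zero
with a warning. The one-off timber windfall (growing stock × commercial
fraction × export price, annualized) is added to every deforested cell
under all scenarios, behind a flag.

Impact: per cell, (TEV + annualized carbon − internalization − AR) × area
deforested, where internalization is the summed person-hours of the six
program-cost categories priced at the national hourly wage and is deducted
only in TEV-based modes (it is a cost of internalizing ES value, so
carbon-only comparisons omit it). Aggregation to country and globe
conserves totals exactly. Cube-root contrasts TEV^⅓ − AR^⅓ use a
sign-preserving root, and uncertainty whiskers transform each replicate's
aggregate *before* taking percentiles.

## The synthetic study system

The generator emulates the analysis inputs at desk scale with a fully
known truth. Countries are contiguous row-major blocks (adjacency is
irrelevant to the method); covariates are independent uniforms over
field-plausible ranges (e.g. 20–30 °C, 1 000–3 500 mm/yr), with an
optional collinearity knob that duplicates one covariate plus noise to
exercise the VIF path. Cells are ~0.1° (12 000 ha); a configurable
fraction (default 0.3) carries Beta(2,5)-distributed loss area; peat depth
is exponential (mean 3 m, truncated at 12 m) on a 10% peat fraction.
Valuation records (default 78 observations across 30 studies) sit on grid
cells and inherit their covariates; log values follow the generative model
with default σ₁ = 0.5 and σ = 1.0 — chosen as the order of spread real
valuation databases show on the log scale — through the *same* design
builder the estimator uses, so recovery tests compare like with like, and
the realized country effects are returned for oracles. Economic tables
draw crop prices around reference farm-gate values with a 15% CV, and the
carbon series/SCC pool are rescaled to means of exactly 13.6 and 30 so the
degenerate no-uncertainty run reproduces the reference prices.

What the generator does not emulate — and therefore what passing tests do
not establish about real data: spatial autocorrelation of loss patches and
covariates, real country shapes, heavy-tailed or censored valuation
values, correlated prices across crops, currency conversion, and
measurement error in the underlying studies. Tests demonstrate that the
*machinery* is correct and calibrated under the stated generative model,
not that the real-world estimates are unbiased.

## Numerical choices and limitations

- Profile-likelihood search over log ρ ∈ [−18.4, 18.4] (bounds 1e−8 to
  1e8), xatol 1e−8; ρ below 1e−7 reported as singular.
- AICc requires n > k + 1 and errors otherwise; enumeration is capped at
  J = 12 (4 096 models).
- MAPE on the log scale is sensitive to observations with |log value|
  near zero; the back-transformed MAPE is provided for such data.
- Through-origin R² uses 1 − Σ(obs − s·pred)²/Σobs².
- Argmax ties and record order are deterministic; reruns of the full
  pipeline under one seed reproduce identical artifact checksums.
- Problem sizes in the suite (grids 10×10 to 50×50, B ≤ 500, M ≤ 2 000)
  are the package's chosen verification scales; all properties tested are
  scale-free or carry explicit sampling-error bands.
- No biodiversity layer, no market-feedback price endogeneity, no land
  degradation or abandonment dynamics, no capital costs, and no
  time-varying social cost of carbon: all are outside the model's scope.
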