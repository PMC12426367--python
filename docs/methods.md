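# Methods

This note documents the statistical models implemented in `fishstab`,
the choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute at run time.

## 1. Stability–asynchrony partitioning (`fishstab.partition`)

All quantities are computed from a species × month matrix for one
region-year. SDs use the **sample (T−1) denominator** throughout. With
only five survey months per year this choice is numerically
consequential for the stability levels `S` and `S̄` (it inflates them
relative to the population denominator by the same factor), while the
dimensionless ratios `ϕ`, `SAE`, `CPE` are nearly invariant to it
because the factor cancels between numerator and denominator. The
sample denominator matches the convention of the variance-partitioning
code circulating in the community-stability literature.

Degenerate inputs raise typed errors instead of returning infinities:

- every `σ_i = 0` (all-constant panel) → `zero-variance`;
- `σ_R = 0` while some `σ_i > 0` (exactly constant totals, i.e.,
  perfect compensation) → `perfect-compensation`;
- `μ_R = 0` → `zero-mean`.

Batch drivers catch these and emit a flagged row with empty metric
cells, so a single degenerate region-year never aborts a run. Species
with `σ_i = 0` but `μ_i > 0` are retained: they contribute to `μ_R`
(and hence to the weighting of `S̄`) but not to `Σσ_i`. `decompose`
asserts `S = ϕ·S̄` and `ϕ = SAE·CPE` to a relative 1e-10 before
returning; these are algebraic identities, so a violation indicates a
numerical defect, not a data property.

## 2. Data model (`fishstab.dataio`)

The interchange format is a tidy long table
(region, year, month, species, quantity_kind, value) with
`quantity_kind ∈ {biomass_kg, harvest_kg, value_usd, trips}` and
non-negative values. Two conventions matter:

- **Zero is data; absence is not.** A closed-season harvest of zero is
  a legitimate row. A missing (species, month) cell makes a panel
  incomplete, and panel construction refuses it with the list of gaps.
  Interpolation of missing survey months is deliberately out of scope —
  gaps must be resolved upstream (e.g., by a model-based index that
  smooths over them).
- **Closure calendars are month-resolved.** A month counts as closed
  when ≥ 15 of its days fall in a closure range (short mid-winter
  closures of a few days therefore do not mask a month). Only the
  March–May closure of the dominant Maryland stock feeds an index, so
  this threshold affects no downstream quantity in the default
  analyses.

Dockside values can be deflated to a base period with a monthly price
index (`value × index(base)/index(year, month)`). Deflation is monthly
rather than annual: monthly indices are what a consumer-price series
provides, and annual deflation of monthly values would mix price levels
across the year before the within-year stability calculation.

## 3. Portfolio indicators (`fishstab.indices`)

- **Seasonal harvest ratio (SHR)**: mean total harvest over
  closure ∩ survey months divided by the mean over survey months
  outside the closure. Both windows are restricted to survey months;
  under the defaults (survey months {3,5,7,9,11}, closure March–May)
  the numerator months are {3,5} and the denominator months {7,9,11},
  so April — closed but unsurveyed — never enters.
- **Harvest timing**: harvest-weighted mean month, over all 12 months
  by default with a survey-months-only variant for comparisons against
  the survey-resolution compensation indices.
- **Effort index**: per species, trips are summed over survey months;
  the index is the unweighted mean of species totals across the
  portfolio species. The alternative reading (mean of monthly trip
  counts) is available behind `per_month=True` without being endorsed
  as the primary definition.
- **Species selection**: species are ranked by multi-year total yield
  (descending, alphabetical tie-break) and included until the
  cumulative share first reaches 90%, inclusive of the crossing
  species. Inclusive crossing keeps low-share species that tip the sum
  over the threshold.
- **Stabilities**: inverse CVs of monthly totals — harvest over survey
  months (short) and 12 months (long), and 12-month value. Degenerate
  (constant) windows yield missing values with paired flags.

## 4. Survey indices (`fishstab.survey`)

The design-based stratified estimator
`Σ_s area_s × mean(catch/swept)_s` stands behind the biomass-index
stage: it is transparent, unbiased under the stratified random design,
and produces the same record type an externally supplied model-based
index would. Its SE uses the standard stratified-sampling variance with
the (n−1) within-stratum denominator; single-haul strata contribute no
variance and are flagged rather than silently treated as exact.
`grid_aggregate` integrates an arbitrary density surface over
equal-area cells (default 6.25 km²) by midpoint quadrature, the same
area-weighting used to convert model predictions to indices.
Coordinates are planar kilometres; no geodesy. Spatiotemporal
random-field index standardization (SPDE/Matérn GAMMs) is out of scope;
downstream analyses are agnostic to how the index was produced.

## 5. Piecewise SEM (`fishstab.sem`)

A path model is a DAG over annual indicator series; each endogenous
variable is a linear sub-model on its parents.

- **Error structures.** iid sub-models use OLS. AR(1) sub-models are
  estimated by **exact Gaussian maximum likelihood**, profiling the
  regression coefficients and innovation variance and optimizing the
  autocorrelation through a tanh-squashed partial-autocorrelation
  parameterization, so every iterate is stationary. Two-step
  feasible-GLS alternatives are unstable at n ≈ 17 annual
  observations, which is why full ML was chosen. Inference uses the
  GLS coefficient covariance with t-tests on n − p residual df.
  Estimates pinned at the stationarity boundary raise an error rather
  than returning a near-unit root.
- **Transforms.** A per-response log transform is applied to the
  response within its sub-model; standardized coefficients
  `β_std = β·sd(x)/sd(y)` use SDs on the modeled (post-transform)
  scales, so a log-scale sub-model standardizes on the log scale. For
  a single-predictor iid sub-model `β_std` equals the Pearson
  correlation exactly.
- **Basis set.** For every non-adjacent ordered pair (u, v) with v
  endogenous and v not an ancestor of u, the implied claim is
  `u ⊥ v | parents(v) ∪ (parents(u) ∩ ancestors(v))`. Unordered pairs
  are deduplicated keeping the claim whose dependent variable is
  endogenous; when both qualify, the topologically later (then
  lexicographically later) variable is the dependent — a deterministic
  tie-break. Claims between two exogenous variables are excluded.
  Every emitted claim is a valid d-separation statement of the DAG
  (verified in tests against a graphical oracle on an enumerated DAG
  suite).
- **Claim tests** regress the claim's dependent variable on its
  conditioning set plus the independent variable and read the latter's
  two-sided p-value. Each claim test inherits the error structure
  declared for its dependent variable's sub-model; whether the original
  analyses did the same for autocorrelated sub-models is not
  documented, so this inheritance rule is a package choice.
- **Fisher's C** `= −2Σ ln pᵢ` is compared to χ² with 2k df; an empty
  basis set (saturated model) returns (0, 0, 1); p-values of exactly
  zero are clamped at 1e-300.
- **Missing years** are removed by complete-case deletion across all
  declared variables, with the dropped years reported in the fit.

## 6. Trends (`fishstab.trends`)

Interannual trends are linear or quadratic in centered year with iid,
AR(1) or AR(2) errors, using the same exact-ML GLS engine (AR(2) via
two partial autocorrelations). The quadratic form is a deliberate
surrogate for penalized smoothers: only a trend's direction and
significance feed interpretation, so spline machinery would add
selection complexity without changing any downstream quantity. The AR
order is configured per series, not selected automatically — visual
residual inspection is not reproducible in code — with AR(1) as the
default. Trends are flagged for display when p < 0.1.

## 7. Synthetic scenarios (`fishstab.synthetic`)

The generator emulates the study conditions of a two-region estuarine
demersal fishery: 17 years, five survey months per year (March, May,
July, September, November), 3–5 species per region with Table-style
baseline magnitudes and prices.

- **Biomass**: `baseline × trend^(y−1) × (1 + a·sin(2πm/12 − φ))`,
  truncated at zero. Sinusoidal annual seasonality is the simplest
  form matching unimodal within-year migration patterns; richer
  phenology is an extension point. A per-year phase-dispersion factor
  (random range × deterministic interannual ramp) contracts species
  phases toward their common mean, controlling seasonal compensation
  year by year.
- **Decline calibration**: per-year multiplicative factors are solved
  (Brent root-finding) so that decade-on-decade mean declines hit the
  configured targets exactly (92%/77%/51% for the three-species
  decline scenario, comparing years 1–9 to years 10–17).
- **Survey**: stratified random hauls in three depth strata, uniform
  within-region density, catches drawn from a compound Poisson–gamma
  (Tweedie) distribution — exact simulation via Poisson count ×
  gamma sums, so no density evaluation is needed — with power 1.5 and
  dispersion 2 by default.
- **Fishery**: monthly effort is shared among open species
  proportionally to `(catchability × biomass × price)^elasticity`
  (elasticity 1 by default). Catchabilities in the presets are set to
  `c/√(baseline × price)`, which makes realized harvest shares track
  biomass shares — the documented regional composition — instead of
  letting effort collapse onto the single most valuable stock.
  Closed species-months receive exactly zero harvest and zero targeted
  trips. During closure months total effort is scaled by a per-year
  participation factor (uniform on [0.2, 1] in the closure preset),
  the behavioral variability that makes the seasonal harvest ratio an
  informative year-level covariate. Harvest noise is multiplicative
  lognormal (CV 0.15); trips are a rounded monotone function of effort
  share with lognormal jitter (CV 0.10), derived from effort rather
  than modeled independently because only their year-scale behavior
  matters downstream.
- **Determinism**: every generator is a pure function of
  (config, seed), with independent RNG streams for community, survey
  and fishery stages.

What the generator does **not** emulate: harvest→population feedback
(the biology is unidirectional by assumption), spatial structure beyond
depth strata, multi-region migration coupling, missing survey cruises,
price dynamics, and fisher-level heterogeneity. Tests that pass on
these scenarios therefore demonstrate that the estimators recover known
mechanisms under controlled asynchrony structure — not that the same
effect sizes hold in real landings data, where index uncertainty,
reporting aggregation and market effects add variance the generator
omits.

## 8. Problem sizes and numerical conventions

Simulation-based tests use: 10,000 lognormal panels for the identity
and oracle suites; 2,000 replicates (n = 17 years) for Fisher's C
calibration and 1,000 for trend type-I rates; 100 seeds per scenario
preset for mechanism recovery; 10⁵ draws for Tweedie moment checks;
200 seeds × 4 phase offsets for the compensation monotonicity property.
These sizes keep Monte-Carlo error comfortably below the tested
margins. Identity assertions use relative 1e-10; bound assertions allow
1e-12 absolute slack for floating-point round-off. AR optimization
bounds partial autocorrelations to |r| ≤ 0.999 (tanh-parameterized);
the AR(1) likelihood is optimized by bounded scalar search and AR(2) by
Nelder–Mead, both ample at these problem sizes.
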