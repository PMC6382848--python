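# Methods

`tgbcover` models fractional tree cover (T) and grass cover (G) in tropical
grassy biomes (TGBs) — savannas and grasslands with a continuous C4 grass
layer — as functions of five per-cell climate and fire variables, and asks
whether intra-seasonal rainfall variability (how often and how hard it rains
within the wet season) carries information about vegetation cover beyond
annual rainfall totals, seasonality and fire.

## Rainfall metrics

All rainfall metrics are derived from a multi-year daily series per grid
cell, on a 365-day year with civil month lengths (Jan = 31, Feb = 28, …).
Leap days are ignored; at the precision of climatological monthly means the
effect is negligible.

- **MAR** (mm y⁻¹): mean over years of the annual total.
- **SI** (dimensionless): Walsh–Lawler seasonality index of the monthly
  climatology `x_m`, `SI = (1/R) Σ_m |x_m − R/12|` with `R` the annual
  total. 0 for uniform rain, 22/12 ≈ 1.83 when all rain falls in one month.
  Undefined (error) for a zero-rain cell.
- **Wet season**: month `m` is wet iff `x_m > p_thr · R/12`, default
  `p_thr = 0.5`. The comparison is strict, so a month exactly at the
  threshold is dry; wet months need not be contiguous, so bimodal regimes
  are represented. `L_w` (d) is the summed length of the wet months.
- **`L_w,SI`** (d): an alternative season length mapped from SI,
  `L_w,SI = 365/12 · (11·(1 − SI/1.83) + 1)` — 365 d at SI = 0, ≈30.4 d at
  the single-month maximum. `calibrate_pthr` chooses `p_thr` by maximising
  the squared Pearson correlation between `L_w` and `L_w,SI` across cells;
  ties go to the first tied candidate in the supplied order.
- **Wet days**: wet-season days with depth > 0.1 mm d⁻¹ (smaller depths are
  treated as measurement noise). **α_w** (mm d⁻¹) is the mean depth pooled
  over all wet days of all years; **λ_w** (d⁻¹) is the mean annual wet-day
  count divided by the climatological `L_w`. Pooling (rather than averaging
  annual means) makes the water balance `MAR_w = α_w·λ_w·L_w + c` exact by
  construction, with `c` exactly the mean annual sub-threshold wet-season
  rainfall. With no wet days at all, α_w is reported as NaN, λ_w = 0 and
  `c = MAR_w`.

An open reading in the λ_w definition — counting wet days against per-year
season lengths versus the single climatological `L_w` — is resolved in
favour of the climatological length, which keeps one `L_w` per cell and the
identity exact.

## Fire metrics

The average fire interval is `AFI = 1/(BA + ε)` years, with `BA` the mean
annual burnt-area fraction and `ε = 10⁻⁴ y⁻¹` capping unburnt cells at
10,000 y. The analysis uses `log10(AFI) = −log10(BA + ε)` because AFI spans
orders of magnitude. Yearly burnt fractions are month sums clipped at 1, so
area re-burnt within a year counts once; this is an approximation to
burn-date-aware aggregation, adequate for fractions well below annual
saturation.

## Cell filtering

From per-cell land-cover class fractions: drop cells with shrubland > 0.5
(the tree-cover product underestimates trees among shrubs); drop cells with
combined human/water plus permanent snow/ice fraction > 1/3 (the threshold
applies to the union of those classes; per-class thresholds are
configurable). TGB cells are those with deciduous-tree + grassland fraction
strictly > 0.5. Surviving cells are labelled by MAR range — R1: MAR ≤ 630,
R2: 630 < MAR < 1200, R3: 1200 ≤ MAR ≤ 2500 mm y⁻¹ — and cells above
2500 mm y⁻¹ are excluded. Boundary conventions (R1 closed above, R3 closed
below) follow the range definitions exactly. Distribution differences
between ranges are tested with two-sided Wilcoxon rank-sum tests
(`scipy.stats.mannwhitneyu`, exact for small tie-free samples).

## Cover models and selection

Cover fractions are fitted as binomial-logit GLMs on predictors
standardized to mean 0, sd 1 (sample sd, ddof = 1), so coefficient
magnitudes are comparable importances. A binomial likelihood needs a trial
count behind each fraction: the default `n_trials = 100` treats cover as a
percentage. Fractions are converted to success counts by rounding; absolute
AIC values depend on `n_trials`, so only AIC *rankings* and coefficient
estimates are meaningful, not absolute AIC levels. Fitting is IRLS via
`statsmodels.GLM` with two-column count responses; an independent
numerical maximizer of the same likelihood serves as an oracle in the test
suite.

The candidate set per response and range contains hierarchical polynomials
of one predictor up to the cubic (lower-order terms always included — this
reading is required for the candidate count to come out right), all ≥2-
predictor combinations with linear terms only, minus any combination
containing both α_w and λ_w (they are tied through the water balance), plus
the intercept-only model: 15 + 18 + 1 = 34 models for the five predictors
{MAR, SI, λ_w, α_w, log10(AFI)}. Models are ranked by
`AIC = −2·loglik + 2·(terms + 1)` (dispersion fixed at 1); ties break
toward fewer terms, then enumeration order. The retained set comprises
models with AIC strictly below the intercept-only model. Goodness of fit is
explained deviance `pseudo-R² = 1 − D_m/D_0`, defined as exactly 0 for the
intercept-only model. For quadratic single-predictor fits
`logit = a + b·z + c·z²` the vertex `z* = −b/(2c)` is reported in natural
units via the stored standardization parameters, labelled a minimum when
`c > 0`.

Note that AIC is not selection-consistent: a spurious extra linear term
enters the best model whenever it lowers the deviance by more than 2, which
under the null happens with probability ≈ 0.157 per candidate term at any
sample size. Exact recovery of a generating term set therefore plateaus
near 70–75%, while recovery of a *superset* of the generating terms is
essentially certain; both behaviours are exercised in the tests.

## Residual collinearity analysis

When a best model contains α_w or λ_w, the analysis checks whether that
dependence is direct or merely mediated by the shared drivers. The cover
fraction is regressed on {MAR, SI, log10(AFI)} (binomial-logit) and the
intra-seasonal variable on the same three predictors (ordinary least
squares — for the normal family, deviance residuals are raw residuals; a
gamma-log alternative can be configured by swapping the predictor-side
model). The squared correlation of the two deviance-residual vectors is the
reported `r²`: near zero means the intra-seasonal term proxies the other
drivers; large means a direct association. If the intra-seasonal variable
is an exact linear combination of the three drivers the pair is flagged
degenerate and `r² = 0` is reported.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the geography of any region:

- **Daily rainfall**: within the configured wet months, each day rains
  independently with probability `event_prob` (the λ_w target) and
  exponential depth with mean `mean_depth` (the α_w target; exponential
  depths match the single-parameter mean-intensity definition, and by
  memorylessness the realized α_w ≈ mean_depth + 0.1). Dry-season days
  drizzle with probability 0.05 and mean 0.5 mm d⁻¹, exercising the wet-day
  threshold without materially moving MAR.
- **Burnt area**: log10(AFI) uniform over a configurable interval,
  inverted through the regularized definition; when the interval reaches
  the cap, ~2% of cells are pinned there, producing exactly-unburnt cells.
- **Land cover**: deterministic allocation of dominant types (78% biome,
  8% shrubland, 8% human/water, 2% snow, 4% other) with random
  within-cell splits; biome-dominant cells are constructed to survive all
  masks, so configured analysis-cell counts are met exactly.
- **Full scenario** (`make_dataset`): cells are allocated per MAR range
  (defaults 694/783/215 — the reference analysis sizes — over 11-year
  series, plus 60 distractor cells that each filter must remove), with
  per-range bounds on target MAR, wet-season month count and event
  probability chosen to give plausible dry/mesic/humid regimes (e.g. R1
  seasons of 4–7 months with λ_w 0.15–0.45). The event-depth mean is solved
  from the target MAR; a cell whose *realized* MAR misses its assigned
  range is redrawn from its own random stream, so the filtered table
  reproduces the configured counts deterministically. Tree and grass cover
  are then drawn from built-in generating logit models on the within-range
  standardized predictors; grass in the humid range, where no predictor
  carries signal, is generated from an intercept only (logit −0.4, ≈ 40%
  cover).

What the generator does **not** emulate: spatial autocorrelation,
orographic structure, sub-daily rainfall, overdispersion of cover beyond
binomial noise, and the constraint T + G ≤ 1 (tree and grass are drawn
independently). Consequently pseudo-R² values on synthetic data run higher
than on satellite data, and passing tests demonstrate correctness of the
pipeline's derivations and inference, not realism of any particular
vegetation prediction.

## Problem sizes and numerical choices

Simulation-based tests use the scenario's own defaults (1692 analysis
cells, 11 years); parameter-recovery checks use 200 generator/refit
replicates at the per-range sample sizes (694 and 215 cells) and selection
checks 100 replicates, sizes at which coefficient standard errors are a few
percent of the generating values. Random streams derive from
`numpy.random.SeedSequence` spawning, so per-cell redraws never disturb
other cells. Degenerate inputs are handled explicitly: zero-rain cells
raise for SI, empty wet seasons are flagged with `L_w = 0`, constant
predictors refuse standardization, and perfect-separation fits are
surfaced via the fitted object's convergence flag.
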