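# tgbcover

Tree and grass cover in tropical grassy biomes (TGBs — savannas and
grasslands with a continuous C4 grass layer) respond to more than annual
rainfall totals: *when* and *how* rain falls within the wet season matters.
`tgbcover` is a Python library for quantifying that dependence. From
per-cell daily precipitation, monthly burnt-area fractions, land-cover
class fractions and fractional tree/grass cover it:

1. derives rainfall metrics — mean annual rainfall (MAR), the Walsh–Lawler
   seasonality index `SI = (1/R) Σ_m |x_m − R/12|`, wet-season length
   `L_w`, wet-day intensity α_w and frequency λ_w, tied by the water
   balance `MAR_w = α_w·λ_w·L_w + c`;
2. converts burnt area to average fire intervals `AFI = 1/(BA + 10⁻⁴)`
   (capped at 10,000 y), analysed as log10(AFI);
3. filters cells (shrubland ≤ 50%, human/water/snow ≤ 1/3, biome fraction
   > 50%, MAR ≤ 2500 mm y⁻¹) and labels three MAR ranges: dry R1 (≤ 630),
   mesic R2 (630–1200) and humid R3 (≥ 1200 mm y⁻¹);
4. fits binomial-logit GLMs `logit(cover) = β₀ + Σ β_j z_j` on standardized
   predictors {MAR, SI, λ_w, α_w, log10(AFI)}, enumerating 34 candidate
   models per response and range (single-predictor polynomials up to cubic,
   linear multi-predictor combinations excluding α_w+λ_w together, and the
   intercept-only model), ranked by AIC with explained deviance
   `pseudo-R² = 1 − D_m/D_0`;
5. checks whether an intra-seasonal term is a direct signal or a proxy, by
   correlating deviance residuals of cover and of the intra-seasonal
   variable after removing MAR, SI and log10(AFI) from both.

A synthetic-data generator reproduces the statistical structure of all
inputs, so the complete pipeline runs and is tested without satellite
downloads. The package is used from Python; the scripts in `examples/`
walk through each capability.

## Worked example

```python
from tgbcover import RainGenParams, compute_metrics, simulate_daily_rainfall

params = RainGenParams(
    n_years=11, wet_months=frozenset({12, 1, 2, 3, 4}),
    event_prob=0.4, mean_depth=10.0, seed=7,
)
m = compute_metrics(simulate_daily_rainfall(params))
```

prints (via `python examples/01_rainfall_metrics.py`):

```
MAR      =    581.7 mm/y
MAR_w    =    577.6 mm/y (wet-season share)
SI       =    1.153
wet months [1, 2, 3, 4, 12]  L_w = 151 d, L_w_SI = 154.3 d
alpha_w  =     9.96 mm/d (target 10 + 0.1 threshold shift)
lambda_w =    0.384 1/d  (target 0.4)
c        =    0.032 mm/y (sub-threshold wet-season rain)
water balance: alpha*lambda*L + c = 577.6 = MAR_w (exact)
```

The five-month season is detected exactly; the two season-length measures
(threshold rule vs SI-mapped) agree within days; realized frequency and
intensity sit at their generating targets; and the water balance closes
exactly, with `c` the few sub-threshold millimetres.

Running the full pipeline on a synthetic scenario
(`python examples/06_full_pipeline.py`) generates the study, re-derives
all metrics from the raw inputs, filters cells, and selects cover models
per range:

```
response mar_range                         model  pseudo_r2
       T        R1                   T ~ 1 + MAR      0.403
       G        R1         G ~ 1 + SI + lambda_w      0.853
       T        R2 T ~ 1 + lambda_w + lambda_w^2      0.839
       G        R2    G ~ 1 + lambda_w + log_afi      0.530
       T        R3               T ~ 1 + alpha_w      0.732
```

Each range recovers its generating model: tree cover driven by MAR when
water-limited (R1), by a parabolic dependence on rainfall frequency in
mesic savannas (R2, with an interior minimum in λ_w), and negatively by
rainfall intensity in humid TGBs (R3). The residual analysis in the same
run reports, per case, how much of the intra-seasonal signal survives after
removing MAR, SI and fire from both sides.

See `docs/methods.md` for the model definitions, generator assumptions and
numerical conventions.

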