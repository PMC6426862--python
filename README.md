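# forestshift

Tools for quantifying century-scale change in the functional composition of
forest tree communities, and for testing whether climate change or
anthropogenic disturbance drives it.

The package targets the classic two-snapshot design of historical-ecology
studies at the temperate–boreal ecotone: preindustrial composition
reconstructed from early land-survey taxa lists (point observations and
short line descriptions along township boundaries), modern composition from
basal-area inventory plots, both aggregated to a 25 km² grid. Because the
original survey archives of such studies are rarely deposited, the package
ships a synthetic-data generator that emulates the full input stack with a
known ground truth, so every stage can be exercised and validated without
any download.

## What it computes

**Community indices.** Each taxon *t* carries four indices: TTI (median
annual temperature over its geographic range, °C), TDTI and TSTI (drought
and shade tolerance on the 1–5 literature scale), and TDI (a 0–11 point
score summing eleven 0–1-scaled disturbance-adaptation traits). After
genus-level averaging and min–max standardization to [0, 1] across the
taxon pool, each grid cell × period gets a community-weighted mean

&nbsp;&nbsp;&nbsp;&nbsp;CI(c) = Σₜ f(c,t)·xₜ / Σₜ f(c,t),

where f(c,t) is the taxon's frequency in the cell: the weight-share of
survey observations mentioning it (historical; weights are line lengths and
mean point spacings in meters) or the share of plots containing it (modern,
after a 3 km proximity filter, genus grouping and removal of taxa under 5%
of plot basal area). Changes ΔCTI, ΔCDTI, ΔCSTI, ΔCDI = modern − historical
lie in [−1, 1] and are directly comparable across indices.

**Drivers.** Per cell: ΔTemperature (OLS slope of mean annual temperature
per year, 1901–1980), ΔSPEI (slope per month of the 24-month standardized
precipitation-evapotranspiration index, built from scratch: Thornthwaite
PET, rolling 24-month water balance, per-calendar-month log-logistic fit by
unbiased probability-weighted moments, normal-quantile transform) and
ΔPopulation (maximum of the 1871/1951/2001 census densities minus 1831,
log₁₀(x+1)-transformed).

**Inference.** Cells are partitioned into spatially connected biogeographic
groups by contiguity-constrained Ward clustering of Hellinger-transformed
preindustrial composition. Index changes are regressed on drivers with
linear mixed models — group random intercepts plus exponential spatial
correlation exp(−d/ρ) among cells of a group — estimated by REML, as a
suite of 4 single-predictor, 4 controlled and 2 cross-index models.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from forestshift import ScenarioConfig, simulate_scenario, run_pipeline

cfg = ScenarioConfig(seed=1)          # 20x20 grid, 17 taxa, disturbance-driven shift
result = run_pipeline(simulate_scenario(cfg))

print(result.deltas.mean().round(3))
fit = result.fits["cdi~pop"]          # Delta CDI ~ log10(Delta population + 1)
print(fit.terms.round(3))
print(f"rho = {fit.rho_km:.1f} km, conditional R2 = {fit.r2_conditional:.2f}")
```

prints

```
delta_cti    -0.024
delta_cdti    0.007
delta_csti   -0.140
delta_cdi     0.127
dtype: float64
                      estimate     se       t     df      p
term
(Intercept)              0.014  0.008   1.868  393.0  0.062
log_delta_population     0.185  0.006  32.643  393.0  0.000
rho = 3.5 km, conditional R2 = 0.86
```

The reference scenario plants a disturbance-driven compositional shift and
no climate effect. Reading the output: the community disturbance index rose
on average by 0.127 (on its 0–1 scale) while shade tolerance fell by 0.140,
and the mixed model attributes ΔCDI to population change with a strongly
significant positive slope (0.185 per log₁₀ unit) — while the same pipeline
leaves the temperature effect on ΔCTI non-significant, correctly separating
the planted driver from the absent one.

## Layout

- `src/forestshift/synthetic.py` — scenario generator with planted truth
- `src/forestshift/ingest.py` — weighting, filtering, grouping, frequencies
- `src/forestshift/indices.py` — taxon indices, standardization, CWMs
- `src/forestshift/drivers.py` — temperature/SPEI/population drivers
- `src/forestshift/models.py` — constrained clustering, spatial mixed models
- `src/forestshift/pipeline.py` — end-to-end wrapper
- `docs/methods.md` — models, assumptions, parameter choices, limitations
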