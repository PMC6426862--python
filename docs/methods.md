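# Methods

This note documents the models implemented in `forestshift`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before trusting
or extending the results.

## Frequency reconstruction from survey records

Historical composition is reconstructed from taxa lists attached to two
kinds of survey records. Every observation receives a weight in meters so
the two kinds are commensurable: a line description weighs its own length;
a point observation weighs the mean of its distances to the previous and
next observation along the same survey line. Two conventions extend the
rule to cases the definition leaves open:

- an endpoint with a single neighbor takes that one neighbor distance
  (unbiased under uniform spacing);
- a point alone on its line has no neighbors and falls back to a
  configurable default spacing of 150 m — the midpoint of the typical
  100–200 m range — and is flagged.

When a point's neighbor is a line observation, the distance is measured to
the line's midpoint. A taxon's frequency in a cell is the weight of
observations mentioning it over the cell's total weight; cells with no
observations are excluded rather than zero-filled. Line observations are
assigned to the cell containing their midpoint; at ~260 m against 5 km
cells the straddling error is negligible.

Modern frequencies are plot-presence shares. Before counting presence,
plots farther than 3 km (inclusive boundary) from every historical
observation are dropped, species are summed into the genus-level taxa that
historical surveyors actually recorded, and taxa strictly below 5% of a
plot's total basal area (computed after genus grouping) are removed — the
filter that makes modern list lengths comparable to the surveyors' habit of
naming only dominant taxa. Exactly 5% is kept. The filter is idempotent by
construction because it never renormalizes retained basal areas.

Only cells present in both period tables enter the change analysis.

## Taxon and community indices

TDI orients each of 11 life-history traits so that larger means more
disturbance-adapted (the orientation is declared trait metadata: high shade
tolerance, long life and late maturity count *against* adaptation), min–max
scales each trait to [0, 1] across the species pool, and sums. A trait
constant across the pool carries no ranking information and contributes 0
to every species, with a warning. Ordinal traits are encoded as integers
before scaling; TDI is therefore invariant to affine changes of raw trait
units but not to monotone nonlinear re-encodings.

TTI supports median (default), mean, 10th and 90th percentile of the
range-masked temperature raster; percentiles use linear interpolation
between order statistics, which is the convention the test oracles assume.
Missing raster pixels are excluded; an all-missing or empty range is an
error.

Index construction order is fixed: species indices → unweighted genus
averages → min–max standardization to [0, 1] across the final taxon pool.
Averaging and standardization do not commute, so the order is part of the
contract. The community-weighted mean divides by the summed frequency of
the taxa that carry the index, which guards against taxa missing from the
index table; with the complete fixture pool this equals the plain total.

## Drivers

ΔTemperature is the OLS slope of annual mean temperature against calendar
year; an incomplete year is an error rather than a silently shorter mean.

The SPEI implementation is self-contained. PET is Thornthwaite's
temperature-only formulation with the standard cubic exponent and a
mid-month solar-declination day-length correction; months at or below 0 °C
have zero PET, and a year whose heat index is zero yields a zero PET year
with a warning. The water balance P − PET is summed over rolling 24-month
windows ending at the indexed month (the first 23 months are undefined).
For each calendar month the window sums over the full series (the reference
period) are fitted with a three-parameter log-logistic distribution via
*unbiased* probability-weighted moments; fitted CDF values are clipped to
[1e-6, 1 − 1e-6] before the standard-normal quantile. Two sample
pathologies are handled explicitly: a constant sample is an error, and a
sample with negative L-skewness — which the right-skewed log-logistic
cannot represent and which does occur in simulated series — is fitted after
reflection (the left-skewed member of the same generalized-logistic
family), using the complementary probability. Calibration (per-calendar-
month mean ≈ 0, sd ≈ 1, severe-drought rate ≈ Φ(−1.5)) is verified on 500
years of stationary simulated climate.

ΔPopulation is max(1871, 1951, 2001) − 1831 census density, accommodating
sub-regions that peaked in different eras. The log transform is
log₁₀(x + 1): base and offset are declared conventions (the offset makes
zero change map to zero). A negative change has no analogue in a
settlement-frontier context; it is retained in the raw column but excluded
(NaN) from the log scale with a warning.

## Spatial mixed models

Biogeographic groups come from agglomerative Ward clustering of
Hellinger-transformed composition profiles with merges restricted to
rook-adjacent cell groups (scikit-learn's connectivity-constrained
implementation), cut at k = 6 by default. The method is deterministic and
every group is connected by construction; a disconnected analyzed-cell set
is an error naming the components.

The regression model is y = Xβ + b_group + ε with b ~ N(0, σ_b²) and
Cov(ε_i, ε_j) = σ²·exp(−d_ij/ρ) within a group, zero across groups, and no
nugget (an option mirrored on the classical exponential correlogram
default). Because both the random intercept and the spatial term are
block-diagonal in the groups, the marginal covariance is processed per
block by Cholesky factorization. REML profiles out β (by GLS) and σ²,
leaving a two-parameter criterion in (log γ, log ρ) with γ = σ_b²/σ²; it is
minimized by Nelder–Mead started from the best point of a coarse 4×4 grid
(γ ∈ {1e-4, 0.1, 1, 10}, ρ ∈ {1, 5, 20, 100} km), which protects against
local optima, and the returned optimum is never worse than any probed grid
point. ρ is constrained to [0.05, 5000] km; a fit at a bound is flagged
`boundary`. A response with zero variance short-circuits to an exact
zero-slope degenerate fit instead of a log(0) failure.

Wald t-tests use a between-within style residual degrees of freedom,
n − (number of groups) − (number of slope terms); with hundreds of cells
the t and normal references are practically identical. Conditional R² is
(var(Xβ̂) + σ_b²) / (var(Xβ̂) + σ_b² + σ²), assigning the spatially
structured variance to the residual — a declared convention, since
published conditional-R² formulas do not uniquely cover residual spatial
correlation.

The model suite fixes ten fits: four single-predictor models (ΔCTI ~
ΔTemperature; ΔCDTI ~ ΔSPEI; ΔCSTI and ΔCDI ~ log ΔPopulation), the same
four with the opposite index family as covariates (climate responses
controlled for ΔCSTI + ΔCDI, disturbance responses for ΔCTI + ΔCDTI), and
two cross-index models (ΔCTI or ΔCDTI ~ ΔCSTI + ΔCDI). The controlled
models keep their focal driver in the design, which is the literal reading
of the suite's description.

Parameter-recovery simulations (β = 0.5, ρ = 10 km, σ_b = 0.5, σ = 1, six
spatial band groups on a 20×20 grid) show near-zero slope bias, ~95% CI
coverage and ~5% type-I error at 200 replicates; σ_b and σ are this
package's choice of a moderate group effect against unit residual noise.

## The synthetic landscape

The generator's defaults define the reference study conditions: a 20×20
grid of 5 km cells (a desk-scale stand-in for the >5000-cell region), six
contiguous clusters, 17 taxa of which four are two-species genus groups, 40
observations and 8 plots per cell, 80 years of monthly climate, censuses in
1831/1871/1951/2001.

Composition: each cluster draws a Dirichlet baseline; cells jitter it in
centered-log-ratio (CLR) space (shared identically by both periods, so it
cancels in Δ). The modern state shifts the CLR vector by
β_dist·z_pop·L_dist + β_temp·z_temp·L_temp + β_moist·z_moist·L_moist plus
spatially correlated noise, then maps back through softmax — simplex
validity is automatic at any effect size. Loadings L are the centered
standardized taxon indices, so the disturbance axis is "toward high-TDI
taxa" by construction, and because the trait fixture builds shade tolerance
anti-correlated with the latent disturbance-adaptation axis, a disturbance
shift also lowers community shade tolerance, as in real systems. Driver
fields are scaled by their spread but *not* centered: every cell with
positive population change shifts toward disturbance-adapted taxa, more so
where change is larger, which is what produces a nonzero mean Δ alongside a
cell-level dose–response. β_dist = 1.5 (CLR units per scaled log-population
unit) is chosen to put the mean ΔCDI near 0.1 on the 0–1 index scale — the
order of magnitude historical studies report — with climate betas zero by
default.

Observation lists use a Plackett–Luce "most abundant taxa" model:
Gumbel-perturbed log-abundance ranking truncated to a list length of
2 + Binomial(3, 0.5) (2–5 taxa; the real length distribution is not
published, so this is a declared assumption). Zero-abundance taxa can never
be listed. Point/line mixture (69/31), point spacing (uniform 100–200 m)
and line length (≈260 m) follow the documented survey geometry; transects
are synthetic west–east lines, not real township boundaries. Plots draw
species-level basal areas from a Dirichlet (concentration 25) around the
cell's modern species abundance times a lognormal total (median 28 m²/ha),
which routinely produces minor species below the 5% filter.

Climate: seasonal cycle ± planted linear trend applied at monthly
resolution (so the annual-mean slope equals the planted slope *exactly*,
giving closed-form trend tests), Gaussian temperature noise (sd 1.5 °C),
gamma-distributed precipitation (shape 4 around a seasonal mean). The
census realizes the planted population change with the peak year varying
randomly across cells to exercise the max-of-three rule.

`true_frequency_tables` evaluates the same list-mention model analytically
(fixed-seed Monte Carlo, a pure function of the abundance vector) for both
periods, bypassing sampling noise; under an all-zero scenario the two
tables are bit-identical and every Δ index is exactly zero end to end.

What the generator does **not** emulate: real township geometry and
surveyor transcription behavior, the actual species pool and its trait
values (all fixture values are synthetic by declaration), spatially
interpolated station climate, and observation-effort gradients. Passing
tests therefore certify the pipeline's arithmetic, calibration and
inferential behavior under a known truth — not the historical accuracy of
any real-world reconstruction.

## Known limitations

- The Wald degrees-of-freedom rule is an approximation; small-sample
  inference (tens of cells) should be treated cautiously.
- The exponential correlogram has no nugget; measurement error at the cell
  scale loads onto ρ, which is typically estimated small when frequencies
  are noisy.
- The reflected log-logistic fallback changes the fitted family for
  left-skewed month samples; SPEI values remain calibrated but are not
  numerically identical to a fit that forces the right-skewed branch.
- Community indices inherit the frequency estimator's bias at low effort
  (few observations or plots per cell); no shrinkage is applied.
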