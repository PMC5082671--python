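# Methods and design notes

This note documents the statistical models implemented in `sswdkit`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Abundance scoring (reef_abundance)

Roving-diver records carry an ordinal abundance per survey × species:
absence (0), Single (1 individual), Few (2–10), Many (11–100),
Abundant (>100). Scores per species × basin × year:

* **Sighting frequency** SF = sighting surveys / all surveys. Absence
  rows therefore must be explicit; `complete_absences` adds them so
  every survey × species pair exists exactly once.
* **Density score** DS = weighted mean of the category codes 1–4 over
  *sighting* surveys only; undefined (reported as `None`/NaN, never a
  silent 0) when the species was never sighted.
* **Abundance score** = DS × SF ∈ [0, 4], defined as 0 when SF = 0.

Filters: habitats in {artificial reef, sandy bottom, eelgrass bed,
mud/silt bottom} are excluded; start time is local clock time in the
closed window [04:00, 22:00]; duration in the closed window [20, 80]
minutes. Boundary values are kept. Year is the calendar year of the
survey date.

The category-to-count transform uses 1 for Single, 101 for Abundant
(lower bound of its open band) and band medians for Few and Many
estimated from calibration surveys that recorded exact counts
(`category_medians`). When no calibration counts are supplied the
defaults are the band midpoints (6, 55.5) — artifact defaults, not
study-derived values. The per-cell mean count averages the transform
over **all** surveys, absences contributing 0; this matches the
interpretation that a cell where the species nearly vanished should
report "close to zero individuals per survey".

## ARIMA projection (projection)

The pre-epidemic series has 8 annual points, so the candidate grid is
deliberately small: p, q ∈ {0, 1, 2} with p + q ≤ 2, d ∈ {0, 1},
intercept always included. A grid search dominates manual ACF/PACF
order identification at this sample size. Selection minimises AICc;
ties (within 1e−6) break by lower ML residual variance, then fewer
parameters — so the intercept-only model wins whenever it attains the
minima, and a constant series selects it outright.

* **Parameter count in AICc**: k = p + q + intercept + innovation
  variance. This convention is fixed and documented because AICc is
  sensitive to k at n = 8; comparisons are only ever made within this
  package, so consistency matters more than the choice itself.
* **Admissibility** replaces informal coefficient inspection: all AR
  and MA polynomial roots must lie strictly outside the unit circle
  (tolerance 1e−6); non-convergent, non-finite or degenerate fits are
  excluded from selection and reported in the failure diagnostics.
* ARIMA(0,0,0)+c is fitted in closed form (mean; variance with divisor
  n — the ML estimate); its forecasts at every horizon equal the
  pre-period mean with standard error √σ². Other orders are fitted by
  Gaussian ML via the statsmodels state-space ARIMA, which chooses
  starting values before optimising — the same two-stage logic as
  conditional-sum-of-squares-then-ML. For d = 1 with intercept the
  trend term is linear in levels, i.e. drift after differencing.
* **Prediction intervals** are Gaussian, point ± 1.959964 · SE(h),
  with plug-in parameter estimates. A value exactly on a bound counts
  as *within*: ties favour the null because "outside" is what licenses
  the biological claim.
* Seasonal terms and exogenous regressors are out of scope (annual
  data).

Interval-coverage calibration is checked by simulation at series
length 100 rather than 8: plug-in prediction intervals ignore
parameter-estimation error, which at n = 8 costs ~3 percentage points
of coverage for *any* correct implementation, while at n = 100 the
deficit is negligible. The replicate-level decline call used in the
detection study is "below the interval in both epidemic years" — a
sustained deviation — which keeps the false-call rate of an unaffected
species near the nominal level while a 95%-mortality epidemic is
detected essentially always.

## Prevalence model (prevalence)

Case definition: white lesions of exposed tissue and/or recent arm
loss; animals in doubt are scored healthy (`classify_star`). Prevalence
is cases/total per group; groups with no stars are absent from the
table rather than reported as 0.

The logistic model uses Henricia spp. and May as reference levels and
is fitted by ML (statsmodels binomial GLM, i.e. IRLS). Complete or
quasi-complete separation is detected as fitted probabilities
collapsing to 0/1 and raised as an explicit error. Factor levels absent
from the data are dropped with a warning instead of producing a
singular design.

* **Contrast families** are separate by default — species (3 pairs,
  Bonferroni m = 3) and months (6 pairs, m = 6) — matching the framing
  "between species and between months"; a combined m = 9 family is
  available. Contrast SEs come from c'Vc on the fitted covariance.
* **Odds-ratio intervals are Wald**, exp(β ± z·SE). Profile-likelihood
  intervals are slightly asymmetric at these sample sizes; Wald is
  chosen for determinism and because the package reports the matching
  z statistics. This is a deliberate, documented divergence from
  profile-based reporting.
* Stars are treated as independent within the single spatial unit; no
  site or transect random effects.

## Density-change model (density_change)

For the j-th taxon on the i-th transect:

    y_ij ~ Poisson(μ_ij),  log μ_ij = log A_ij + α_j + β_j·Year_i + ε_ij

with A_ij the surveyed area in m² (offset), Year_i ∈ {0, 1} for
2014/2015, ε_ij ~ N(0, σ_ε) observation-level overdispersion, and
(α_j, β_j) bivariate normal with means (μ_α, μ_β), SDs (σ_α, σ_β) and
correlation ρ. α_j is the taxon log density *per m²* in 2014; densities
are reported per 100 m² only at the presentation layer. Priors:
N(0, 10 000) for the means — variance 10 000, i.e. SD 100, the
precision-10⁻⁴ convention of BUGS-dialect samplers — U(0, 100) for the
three SDs, U(−1, 1) for ρ. "N(0, σ_ε)" is read with σ_ε as a standard
deviation, consistent with its U(0, 100) prior.

The model statement composes a single area offset: the Poisson mean is
A·exp(α + β·Year + ε). This is the only reading under which α is a log
density per m² and under which scaling every area by c shifts every
α_j by −log c while leaving every β_j unchanged (the offset contract,
verified by test).

**Sampler.** Adaptive Metropolis-within-Gibbs, vectorised in numpy:

* per-taxon random-walk updates of α_j and β_j, each component with its
  own adaptive scale (slopes of taxa unseen in one year are weakly
  identified and need much wider proposals than intercepts);
* element-wise vectorised random-walk updates of all ε_ij;
* an exact bivariate-normal Gibbs draw of (μ_α, μ_β) (conjugate given
  the taxon effects and Σ);
* scalar random-walk updates of σ_α, σ_β, ρ against the taxon-effect
  likelihood;
* an exact Gibbs draw of σ_ε² | ε (inverse-gamma under the uniform
  prior on σ_ε), plus a **non-centered rescale move** that proposes
  σ_ε′ = σ_ε·e^z and ε′ = ε·(σ_ε′/σ_ε) jointly. Holding ε/σ_ε fixed
  makes the ε-prior ratio cancel the Jacobian exactly, leaving the
  Poisson likelihood ratio times the change-of-variables term
  (σ_ε′/σ_ε). This move is what breaks the funnel at σ_ε → 0 when the
  data carry little overdispersion; without it the σ_ε chain is the
  only non-converging parameter (R̂ ≈ 1.8 observed, vs ≤ 1.01 with it).

Proposal scales adapt toward 20–40% acceptance during burn-in only
(factor 1.25 up / 0.8 down every 50 iterations, clipped to
[10⁻³, 10]), so retained draws come from a fixed kernel. Start values
follow the study's dialect: N(0, 1) for means and ε, U(0, 1) for the
SDs and ρ. Chains are reproducible: per-chain seeds derive from the
config seed via `SeedSequence.spawn`.

The study-scale chain configuration is 3 chains × 60 000 post-burn-in
iterations after 10 000 burn-in with thinning 5 (30 000 retained
total); the package default is a desk-scale 3 × 6 000 / 1 000 / 5 used
by the pipeline and tests, with the full setting available through
`ChainConfig.study_scale()`. Retention applies thinning to post-burn-in
iterations, the only arithmetic under which 3 chains retain 30 000.

**Diagnostics.** `gelman_rubin` is the classic potential scale
reduction factor √(((n−1)/n·W + (m+1)/(mn)·B)/W); a warning threshold
of 1.05 is used (slightly stricter than the 1.04 the study reported;
chains are never auto-extended). `effective_sample_size` uses
FFT autocorrelations with Geyer initial-positive-sequence truncation;
for AR(1) draws it reproduces the closed form n(1−φ)/(1+φ).

**Decision rule.** A taxon's density change is a *credible
decline/increase* when the equal-tailed 95% credible interval of β_j
excludes zero. "Borderline" is not given a second threshold: the
posterior decline probability P(β_j < 0) is reported per taxon so
near-credible cases (taxa nearly absent in the second year) are
visible without inventing one.

With a single taxon the hyperparameters are unidentifiable and act
only as a vague prior; `run_mcmc` warns but proceeds, since the
single-taxon configuration is the natural oracle check (its β posterior
must match the closed-form log rate ratio of the two years). An empty
dataset recovers the priors exactly.

## Synthetic data (synthetic_data)

The generators emulate the *statistical structure* the analyses assume,
at the study's scale:

* **Roving surveys**: per basin × year survey counts default to the
  published effort table (8 097 surveys, 2006–2015, 5 basins + outer
  coast). Each species has a latent yearly mean count following a
  stationary AR(1) on the log scale (mean-corrected so the marginal
  mean equals the configured baseline), multiplied by an epidemic
  survival fraction from the onset year (2014) onward. Per-survey
  counts are negative-binomial (gamma-Poisson) around the yearly mean —
  Poisson alone cannot produce the observed mix of Few/Many records at
  realistic means — then binned to the ordinal categories with the same
  boundaries the scorer assumes. Default species settings: sunflower
  star baseline 9.9 per survey with 5% survival (its pre-epidemic mean
  count and post-epidemic collapse), giant pink star 0.6 with 30%
  survival, leather star 2.0 unaffected. A configurable fraction of
  surveys (default 10%) deliberately violates one inclusion rule so
  filter tests are non-vacuous.
* **Strip transects**: 8 named sites × May–August × {2014, 2015},
  two 100 m² belt transects per site-month by default. Taxon counts are
  Poisson(area/100 × density), with 2015 density scaled by
  exp(log-density change); default densities are the published 2014 and
  2015 values per taxon (taxa absent in one year get a large negative
  or bootstrapped-from-0.01 change). Disease status is Bernoulli with
  logit = intercept + species effect + month effect; defaults are the
  published logistic coefficients, so simulated prevalence ramps from
  May to August and differs sharply by species.
* **Calibration counts**: arbitrary count distribution per expert
  survey, for the category-median transform.

Not emulated: spatial point processes, diver detectability beyond the
categorical binning, observer heterogeneity, within-year disease
progression in the roving data, and site-level density differences.
Passing tests therefore demonstrate correctness of the *estimators
under their assumed models*, not robustness to field realities such as
detection bias or spatial clustering.

One RNG stream per generator, seeded from the config; per-basin and
per-site substreams are spawned deterministically, so outputs are
byte-identical across runs with the same seed.

## Problem sizes in tests and the acceptance script

Simulation studies run at sizes chosen to make sampling error small
relative to the tolerances they check: forecast-interval coverage uses
4 000–10 000 replicates of length-100 series (closed-form fits);
decline detection 20–30 replicates of a 60-survey basin; logistic
recovery 40 replicates of 5 000 stars; hyperparameter recovery 50
replicates of 10 taxa × 40 observations with single desk-scale chains;
the study-scale density-change run uses 3 × 20 000 iterations. The
σ_ε used in recovery simulations is 0.5 (moderate overdispersion);
the published summary reports no value for it.

## Known limitations

* The ARIMA stage's intervals are plug-in; at n = 8 they undercover by
  a few points, exactly as any implementation without
  estimation-uncertainty corrections would. Bootstrap or Bayesian
  intervals would fix this at the cost of comparability.
* The prevalence model's Wald intervals differ in the third significant
  figure from profile intervals at study sample sizes.
* The sampler is a random-walk scheme; for much larger datasets a
  gradient-based sampler would scale better. At the study's size
  (≈1 300 observations, 10 taxa) full runs take well under a minute.
* Basin assignment, mapping and any re-analysis of the original
  (undeposited) field records are out of scope; `reference.py` carries
  only printed tables used as inputs.
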