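# Methods

This note documents the models behind `cotspred`, the choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Synthetic survey generator (`cotspred.simulate`)

`generate_survey` draws belt transects hierarchically (region → reef → site
→ transect). The default design mirrors the field study's shape: 6 southern
sites × 9 transects of 120 m², 2 central sites × 3, and 8 northern sites × 7
transects of 40 m² (54/6/56 transects). Variables are generated causally:

- **Depth** (m): site mean uniform on the configured range (default 2–10 m)
  plus transect jitter (SD 0.6 m).
- **Benthic cover** is logistic-normal: per-category Gaussian latents around
  the log of configured mean weights (latent SD 0.5), softmax-normalized so
  the seven proportions sum to one exactly. A `depth → sand` path adds the
  coefficient times z-scored depth to the sand latent.
- **Path semantics.** A continuous child is
  `mu + sigma * (Σ_j beta_j z_j + sqrt(1 − Σ beta_j²) ε)`, so a configured
  coefficient is recovered as the empirical standardized regression slope
  (checked to ±0.05 at n = 5,000). Children are clipped below at physical
  bounds; location/scale defaults (bed thickness 12 ± 4 cm, 47 ± 18 pieces,
  160 ± 50 cm² pieces, CoTS index 1.0 ± 0.3) keep clipping rare enough not
  to bias slopes measurably.
- **Predator counts** are zero-inflated negative binomial. The conditional
  log-mean is `log(density × area/100 / (1 − π))` plus path terms, a site
  random intercept (SD 0.25 on the log scale), and a lognormal mean
  correction `−(Σβ² + σ_site²)/2` so regional expected densities stay on
  target. Default zero-inflation is 0.25 for *S. aspera* and 0.20 for the
  crab families; NB dispersion θ = 1.5 (counts are strongly overdispersed
  and zero-heavy, as in rarely encountered cryptic fauna).
- **Regional density defaults** (ind./100 m²) were calibrated once by
  inverting the published community predation rates with the published
  per-capita consumption rates: south total ≈ 3.6 (S. aspera 0.73), central
  ≈ 2.0 (0.20), north ≈ 3.6 (0.05). These make the rate-weighted community
  totals average ≈ 5.4 / 1.9 / 1.7 ind. 100 m⁻² d⁻¹ and the realized rates
  ≈ 0.6 (south) and 0.4 (north) at a one-day window — the regime the
  downstream estimators are meant to operate in.

`generate_feeding_trials` uses a logistic decay
`p(t) = p0 · σ(s(h − t)) / σ(s·h)` with `p(0) = p0` and `p(h) ≈ p0/2`.
Defaults `p0 = 0.99`, `h = 40 h`, `s = 0.09 /h` put mean detection within
12 h near 97% and detection at 48 h near 1/3. Copy numbers are log-normal
(SD 0.8 in logs) around a gamma-shaped curve with mode at 10.5 h (between
9 and 12 h). Droplet counts are drawn from the copies-implied per-droplet
concentration and forced consistent with the detection flag. `exact=True`
replaces Bernoulli draws with expected-count rounding per time group (the
deterministic fixture used in worked examples: 3/3, 5/5, 2/2, 3/3, 1/3).

`generate_specimen_screen` produces per-region screening records;
`exact_counts=True` forces `round(n × p_pos)` positives. Defaults are 12
southern *S. aspera* at 2/12 and 63 northern decapods at 7/63.

**Not emulated:** spatial autocorrelation between transects, tides or
seasonality, species-level variation within crab families, partial or
multiple prey consumption, inhibition or contamination in the assays.
Passing tests therefore demonstrate correctness of the estimators under the
declared generative model, not robustness to these field realities.

## Zero-inflated count models (`cotspred.counts`)

Densities are counts with a `log(area/100)` offset, so fixed effects act on
the per-100 m² density scale (`use_offset=False` supports pre-standardized
responses). The model is a mixture of a structural zero (probability π, one
parameter, no covariates) and Poisson or negative-binomial counts with a log
link, region fixed effects (treatment coding), and a Gaussian site random
intercept on the count component only.

The marginal likelihood integrates the site effect by **adaptive
Gauss–Hermite quadrature** (default 9 nodes): per-site posterior modes by
safeguarded Newton (analytic first and second derivatives of the ZI
log-likelihood with respect to the linear predictor, vectorized across
sites, warm-started between likelihood evaluations), then nodes centred and
scaled by the mode and curvature. Optimization is L-BFGS-B from a
moment-based start plus jittered restarts (default 3); convergence tolerance
is the optimizer default with bounds keeping π, θ and σ_site in numerically
safe ranges. The covariance of the fixed effects is the inverse numerical
Hessian at the optimum; failures set `converged=False` rather than raising,
except the all-zero response which raises a structured degenerate-data
error.

A deliberate deviation from the source analysis: the field study fitted a
zero-inflated Tweedie to pre-standardized densities. Counts-with-offset
ZINB/ZIP targets the same inferential quantity (region effects on density)
with a fully self-contained likelihood; Tweedie density evaluation is out of
scope.

`region_test` is the asymptotic Wald chi-square on the region coefficients
(df = levels − 1). It is asymptotic in the number of *sites*: with very few
sites per region it is visibly anticonservative, so the calibration test
runs at 12 sites × 8 transects per region. `pairwise_contrasts` adjusts
pairwise marginal-mean differences with the studentized-range distribution
at infinite df (the z-based Tukey adjustment conventional for mixed models
without a finite residual df) and emits a compact-letter display computed as the
maximal cliques of the non-significance graph — two levels share a letter
iff their adjusted p exceeds α. A randomized-quantile-residual PIT check
(site effect at zero) stands in for a full residual-diagnostic workflow.

## Bayesian path model (`cotspred.sem`)

A recursive linear Gaussian SEM: every endogenous variable is regressed on
its declared parents; continuous variables are z-scored so coefficients are
standardized path effects; categorical spatial drivers (reef, site) enter as
sum-to-zero contrasts; no interactions or latent variables (component models
are purely additive). Residuals are independent across equations except
within declared blocks — by default the four cover categories, whose
compositional dependence is captured as a freely estimated residual
covariance (seemingly-unrelated-regressions structure).

Priors: N(0, 1) on every coefficient; inverse-gamma(2, 1) on singleton
residual variances; inverse-Wishart(m + 2, I) on block covariances. The
Gibbs sampler alternates conjugate Gaussian coefficient draws (jointly
across a block given its covariance) with variance/covariance draws
(inverse-Wishart via Bartlett decomposition). With the residual variance
fixed, the coefficient posterior mean is exactly the ridge closed form
`(X'X + σ²I)⁻¹X'y` — the oracle the tests check against. Default run length
follows the study settings (3 chains × 11,000 iterations, 1,000 burn-in);
tests and the reduced pipeline mode use 3 × 2,000 with 500 burn-in, which
reaches R-hat ≤ 1.05 on the default graph at the default survey size.

The default graph reconstructs the study's structure: depth/reef/site →
{rubble, live-coral, dead-coral, sand cover} → {bed thickness, piece size,
piece count} → {*S. aspera*, portunids} → CoTS index. "Hard substrate" as a
driver of *S. aspera* has no measured column; dead-coral cover is its
declared stand-in. Significance is a 95% central credible interval excluding
zero (the source's criterion is not stated; this is the conventional
reading of its significant/nonsignificant arrows).

Diagnostics: rank-normalized split R-hat (via `arviz`; at least 2 chains and
100 retained iterations required). The posterior-predictive p-value
simulates replicate data at the observed designs for each retained draw and
compares a discrepancy. The default discrepancy is the total squared
standardized residual (Mahalanobis within blocks). Because residual
variances are free parameters, this statistic is variance-adaptive and has
essentially **no power against symmetric heavy-tailed misspecification**;
`statistic="tails"` (total fourth power of standardized residuals) is
provided for exactly that alternative, and the misfit test uses it. The
source's reported p-value is not treated as reproducible since its
discrepancy is unstated.

## eDNA metrics (`cotspred.edna`)

Positivity is ≥ 1 positive droplet in any replicate (all controls clean, so
no threshold beyond a single droplet). Quantification follows digital-PCR
Poisson occupancy: λ = −ln(1 − k/N) copies per droplet per replicate;
replicate concentrations are averaged and scaled to copies per sample by the
volume constants in `DdpcrConfig` (0.85 nl droplets, 25 µl reactions, 5 µl
template from a 150 µl elution — all configurable; `extract_fraction` is the
per-replicate template fraction). Saturated assays (k = N in every
replicate) raise rather than extrapolate. In the small-occupancy limit
λ ≈ k/N within 1% for k/N < 0.01.

The decay model is logistic-linear in hours (the source names no curve;
this choice is validated by monotonicity and parameter-recovery properties
only), fitted by binomial ML via statsmodels GLM. Complete or
quasi-complete separation (e.g. every specimen positive) falls back to a
Firth/Jeffreys-penalized Newton fit, flagged via `separation=True`; the
penalty shades fitted probabilities at the extremes of the observed range
slightly toward ½, which is why the degenerate all-positive fixture fits
≈ 0.88 at 48 h rather than ≥ 0.9.

Merged-tissue assays (one record per specimen) are the default, matching
the study's pooling of stomach, midgut and abdomen before extraction.

## Predation scaling (`cotspred.predation`)

`clopper_pearson` is the exact Beta-quantile interval (what R's
`binom.test` reports); tests verify it against numeric inversion of the
binomial tails for all k ≤ n ≤ 30 and ≥ 95% coverage on a 0.001 p-grid.
Potential predation applies the published consumption rates (5.8 ind d⁻¹
for *S. aspera*; the portunid 0.4 ind d⁻¹ reused for xanthids and
epialtids) per transect and summarizes per region (mean, median, quartiles,
max). Realized predation `RP = D·(k/n)/d` treats D as fixed (as the source
does) and propagates only the exact interval on pDNA; the
one-juvenile-consumed-in-full assumption is recorded on the estimate as
`whole_prey=True`. Default windows d ∈ {1, 2} days. Whether D should be the
screened-taxa density or the whole community's is not settled by the
source; the pipeline uses the community total (which is also what the
published realized rates imply) and the API accepts any D.

## Pipeline (`cotspred.pipeline`, CLI `cotspred`)

One root seed feeds named per-stage substreams (all < 2³¹), recorded in
`provenance.json`; equal config + seed reproduces `summary.json` byte for
byte. Every number in the summary is read back from a stage output table by
the test suite (no report-only computation). Validation checks schema and
invariants (cover sums, count integrality, droplet bounds, flag/droplet
consistency) and reports row-level findings without dropping rows.

## Problem sizes used in testing

Monte-Carlo checks run at the smallest sizes that make their tolerances
meaningful: generator moment checks at n = 5,000–10,000 transects; ddPCR
round-trip at 1,000 simulations of 15,000 droplets; SEM coverage over 50
studies of n = 500 at 3 × 2,000 chains; count-model recovery at n =
300/region; Wald calibration over 500 surveys of 12 sites × 8 transects per
region; the pipeline's own runs use the study-shaped design (116 transects)
with reduced chains.

## Known limitations

- The count likelihood integrates one Gaussian random intercept; crossed or
  nested (reef/site) random effects are not supported.
- The SEM assumes Gaussian residuals on z-scored observed variables; count
  nodes enter as standardized densities, so their sampling noise attenuates
  downstream path estimates at small n (visible in the pipeline's
  predator → CoTS edge versus the generator's configured value).
- Realized predation ignores uncertainty in D (an optional bootstrap is a
  natural extension) and assumes exactly one whole prey per positive
  specimen within the window.
- The generator's calibration reproduces regional *means*; it does not
  attempt the field data's full spatial covariance, so test tolerances on
  regional summaries are necessarily stochastic-scale.
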