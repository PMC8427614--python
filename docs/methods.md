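# Methods

## The model

`mastmix` estimates small-mammal abundance from repeated nightly capture
counts with imperfect detection, using a Poisson-lognormal binomial
N-mixture model. A *session* i is a block of 2–5 consecutive trap nights at
one site, assumed demographically closed; sessions at least 35 days apart
are treated as open to population change and enter the likelihood as
independent replicates (time-for-space substitution). For session i with
nights j = 1..J_i:

    N_i        ~ Poisson(A_i · λ_i)
    log λ_i    = β₀ + β_site(i) + β_F·F_i + β_C·K_i + β_J·J_i + β_J²·J_i²
                 + β_{site(i):F}·F_i + ε_i
    ε_i        ~ Normal(0, σ_ε),  τ = σ_ε⁻²
    C_ij | N_i ~ Binomial(N_i, p_ij)
    logit p_ij = α₀ + α₁·night_ij + α₂·T_ij + α₃·T_ij² + α₄·R_ij + α₅·T_ij·R_ij

where F and K are the standardized log seed-rain covariates (beech and
pooled conifers), J the standardized Julian day of the session midpoint, T
the standardized mean night temperature (19:00–06:00 of the preceding
night), R the standardized previous-day precipitation sum, and night the
standardized 1-based night-of-session index. A_i is the sampled grid area
in hectares, so λ_i is density in individuals per hectare.

**The offset is applied exactly once.** Writing the hierarchy with the area
both inside the Poisson rate and in the linear predictor would count A_i
twice; the implementation fixes E[N_i] = A_i·exp(x_iᵀβ + ε_i), which makes
λ_i interpretable as density. This choice is deliberate and prominent
because it is easy to get wrong.

Equal detection probability is assumed for all individuals of a taxon
within a night; each taxon is modelled separately.

## Covariate construction

* Seed densities: per-trap annual totals / 0.24 m² trap basal area, averaged
  over the 81 traps of a landform stratum; spruce and fir are pooled per
  trap before averaging (the mean is linear, so pooled-then-average equals
  sum of per-species averages — tested).
* Log transform: log(1+x). A plain log of mean seed density is undefined in
  zero-crop failure years; the +1 offset keeps the transform total and maps
  0 to 0. Reporting back-transforms with expm1.
* Masting-period alignment: a session trapped in calendar year y is driven
  by the seed crop of autumn y−1 through spring y, labelled period y−1.
  October sessions therefore use the *previous* crop, consistent with
  fixing the seed-rain date at 1 July of the year after seed production.
* Landform sharing: seed rain is monitored at one plot per landform; all
  sites of a landform inherit its series (basin → PFb, MFb; slope → PFs,
  WTs, AVs).
* Standardization: (x − mean)/sample-SD over the fitting set; the squared
  Julian and temperature terms are squares of the standardized base
  covariate; night-of-session is standardized like any other continuous
  covariate. Centers and scales are stored with the fit so effect axes can
  be back-transformed.
* Grid area: n_stations × spacing² (each station credits one
  spacing×spacing cell); 25 stations at 15 m → 0.5625 ha, the 44-station
  elongated grid → 0.99 ha.
* Sessions whose landform/period has no seed-trap data are excluded with a
  logged report, never silently (count in = count kept + count excluded).
  An imputation hook is left unimplemented.

## Posterior simulation

Metropolis-within-Gibbs, one sweep per iteration:

1. each latent N_i by a symmetric integer random walk (step ~
   Uniform{−m..m}\{0}, m adapted per session) bounded below by max_j C_ij;
2. each ε_i by Gaussian random-walk MH;
3. τ by its conjugate Gamma draw given ε;
4. β and α coordinate-wise by Gaussian random-walk MH;
5. a joint "trade" move shifting β₀ up and α₀ down by the same amount
   (several per sweep). The abundance and detection intercepts are strongly
   negatively correlated in N-mixture posteriors (more animals seen less
   often explains the same counts); the trade move traverses this ridge and
   roughly halves the R-hat of the two intercepts at fixed cost.

Priors are diffuse: Normal(0, variance 1000) on all coefficients,
Gamma(0.001, 0.001) on the precision τ (configurable). Initial values:
coefficients ~ Normal(0,1), N_i = max_j C_ij + Poisson(5), ε = 0;
non-finite initial states are redrawn (bounded retries). Proposal scales
adapt by Robbins-Monro multiplicative steps towards 30 % acceptance (40 %
for the latent integers) during the burn-in/adaptation phase only and are
frozen afterwards, so the retained chain is Markovian. Detection
probabilities are clipped to (1e−12, 1−1e−12) inside the sampler caches to
keep log-likelihood differences finite.

The field-scale protocol (3 chains × 800,000 iterations, 100,000
burn-in/adaptation, thinning 200 → 10,500 retained draws) is the config
default; experiments in this package run a desk-scale protocol of
3 × 20,000 / 4,000 / 10 (4,800 retained draws), which the recovery
experiment shows is enough for interval coverage at the nominal level on
studies of ~120 sessions. Runs are bit-reproducible given the seed; chains
use independently spawned generator streams.

Convergence: the classic Gelman–Rubin/Brooks–Gelman potential scale
reduction factor on unsplit chains, R̂ = sqrt(var⁺/W + B/(n·m·W)) with
var⁺ = (n−1)/n·W + B/n, flagging parameters at R̂ ≥ 1.1; effective sample
sizes come from arviz. The `fixed=` argument of `fit` pins any parameter
block, which is how the sampler is validated against exact enumeration of
the latent-abundance posterior (total variation < 0.02 on toy data).

## Goodness of fit

Per retained draw, expected nightly counts are E_ij = N_i·p_ij
(conditioning on the sampled latent abundance — the standard N-mixture
posterior-predictive construction; the discrepancy is computed on nightly
counts, the scale of the binomial layer). The discrepancy is Pearson's
chi-square with a guard of 0.5 in the denominator against near-zero
expectations. The Bayesian p-value is the share of draws whose fresh
binomial replicate exceeds the observed discrepancy strictly (ties count
as not exceeding — this matters only in degenerate cases); c-hat is
mean(D_obs)/mean(D_rep).

Calibration is assessed by checking fits against their *own* data, which
were generated from the model: the check must not flag them (p away from 0
and 1, c-hat near 1). Scoring a fresh posterior-predictive dataset against
an existing fit without refitting is deliberately avoided: the retained
latent abundances are conditioned on the original counts, so that
comparison inflates the observed discrepancy (we measured median c-hat
≈ 1.6 and p-values ≈ 0) and would misreport the check's calibration.

## Synthetic studies

The generator emulates a five-site montane trapping study: PFb, MFb
(basin), PFs, WTs, AVs (slope); 25-station square grids at 15 m spacing
except a 44-station elongated grid at the avalanche site; 1–3 sessions per
year anchored between mid-May and early October (jitter ±5 d, spacing
≥ 35 d); 2–5 nights per session; 16 years by default (12 in the recovery
scenario).

Seed rain: each species' annual density is a two-part lognormal mixture —
ordinary years around a base median (beech 5, conifers 2.5 seeds/m²,
log-SD 1.0) and mast years (probability 0.3) at 50× the median (log-SD
0.7). The four margins (2 species × 2 landforms) are coupled by a Gaussian
copula whose correlation is the Kronecker product of a species block (0.7)
and a landform block (0.9), matching the strong basin–slope synchrony and
positive beech–conifer association of real masting series. Per-trap counts
are negative binomial (k = 0.7) around the stratum mean, 81 traps per
landform. These defaults put interannual beech variation at two or more
orders of magnitude over 15-year windows, the regime the analysis is
designed for.

Weather: night temperature AR(1) within session (mean 8 °C, SD 4 °C,
φ = 0.7); precipitation Bernoulli(0.4) × Gamma(1.5, scale 6 mm) — a
montane-summer range, configurable.

True parameters default to the magnitudes such a field study estimates
(λ-intercept 3.0, conifer effect 0.27, Julian ±0.1/−0.22, site effects
+0.1 for canopy sites and −0.93/−2.85 for the windthrow and avalanche
sites, σ_ε = 0.5; detection intercept −1.08 with small weather effects).
The beech response encodes the spillover structure: canopy sites respond
weakly (slope 0.20–0.25 per SD of log seed rain) while the open sites
respond steeply (WTs +0.55, AVs +0.73 interaction contrasts), so the open
sites sit far below the canopy sites after seed failures and converge
towards them after mast years. Expressed against an interaction factor
referenced the other way, this is a single negative canopy-contrast
coefficient — the form in which such a table usually prints one
"site × beech seeds" row. Both interaction codings (one column per
non-reference site; or a single pooled open-site indicator) are available
in the design builder.

What the generator does *not* emulate: between-session population dynamics
(sessions are exchangeable given covariates), trap saturation (counts are
unbounded binomials; the data layer only warns when a count exceeds
2 traps × stations), behavioural responses to capture, species
misclassification, and spatial autocorrelation among traps within a grid.
Passing recovery tests therefore demonstrate estimator correctness under
the model's own assumptions, not robustness to their violation.

## Experiments the package ships

* **Parameter recovery** — 20 replicates of generate → fit → score on the
  5-site × 12-year scenario at the desk-scale MCMC protocol; each replicate
  draws its own effect sizes (beech ~ N(0.5, 0.35), conifer ~ N(0.3, 0.2),
  detection intercept ~ N(−1.0, 0.3)). Reported: 95 % interval coverage,
  truth–estimate correlation, RMSE. Individual replicates can land several
  posterior SDs from the truth (the N–p split is weakly identified at
  p ≈ 0.25 with ~120 sessions — a known N-mixture property, visible in the
  worked example); coverage across replicates is the meaningful metric.
* **GOF calibration** — 50 checks cycling over the recovery fits with fresh
  replication seeds (see above).
* **Sampler validation** — total-variation comparison against exact
  enumeration on a two-session toy with coefficients pinned at truth.
* **Spillover structure** — one fit under the default truth; per-site
  marginal-effect curves must rank the open site lowest at low seed rain
  with a monotonically narrowing log-density gap towards every canopy site.

## Numerical choices

* Quantiles: linear interpolation (numpy default), pooled across chains.
* `excludes_zero`: both 95 % interval endpoints share one sign.
* Marginal effects: ε set to its median 0, all other standardized
  covariates at 0; density reported per hectare (offset excluded).
* Enumeration oracle truncation: N_max chosen so the discarded Poisson tail
  is < 1e−12 in tests; the normalization check sums to 1 within 1e−8.
* Julian day of a session is the day-of-year of the session midpoint
  (fractional for even night counts).
* CSV round-trips write floats at %.17g and read with round-trip precision,
  so write → read is the identity on studies.

## Known limitations

* Single-taxon fits only; no shared parameters across taxa.
* No imputation for sessions lacking seed data (excluded with a report).
* The coordinate-wise random-walk sampler mixes slowly for strongly
  correlated coefficient pairs beyond the intercepts; the trade move
  addresses the dominant ridge only.
* τ's posterior is heavy-tailed when few sessions inform it; desk-scale
  runs can flag τ/σ_ε at R̂ ≈ 1.1–1.2 on small studies even when the
  regression coefficients have converged.
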