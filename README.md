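# mastmix

Hierarchical Bayesian N-mixture models for mast-seeding-driven small-mammal
trapping studies.

Granivorous forest rodents (wood mice, bank voles) boom after tree mast
years and their habitat use shifts with density: open gaps that voles avoid
after seed failures fill up after full mast. Estimating those density
responses from live-trapping data requires separating *abundance* from
*detection* — a night with few captures can mean few animals or shy ones.
`mastmix` implements the standard solution for unmarked repeated counts:
the Poisson-lognormal binomial N-mixture model, fitted by MCMC, driven by
seed-rain and weather covariates.

For session i (a closed block of 2–5 consecutive trap nights at one site)
with nightly captures C_ij:

    N_i        ~ Poisson(A_i · λ_i)                    latent abundance
    log λ_i    = x_iᵀβ + ε_i,   ε_i ~ Normal(0, σ_ε)   density [ind/ha]
    C_ij | N_i ~ Binomial(N_i, p_ij)                   imperfect detection
    logit p_ij = z_ijᵀα

with an area offset A_i, site factor, standardized log seed-rain covariates
(beech; pooled conifers), Julian-day terms and a site × beech-seed
interaction in x; night-of-session, night temperature and previous-day
precipitation terms in z. See `docs/methods.md` for the full model,
priors, sampler and design notes.

The package covers the whole pipeline: canonical CSV study tables →
covariates and design matrices → Metropolis-within-Gibbs posterior
simulation → convergence diagnostics → posterior-predictive
goodness-of-fit (Bayesian p-value, c-hat) → coefficient tables and
marginal-effect curves. A synthetic-study generator reproduces the
statistical structure of a five-site montane masting study and powers the
parameter-recovery and calibration experiments.

## Worked example

`examples/02_fit_and_diagnose.py` generates a 12-year synthetic study
(119 sessions, 945 captures), fits it with the desk-scale protocol
(3 chains × 20,000 iterations) and prints posterior summaries next to the
generating values:

```
parameter                           posterior   truth  rhat
lambda:intercept               +2.24 +- 0.18    +3.00  1.002
lambda:site[AVs]               -1.65 +- 0.29    -2.85  1.000
lambda:fagus_seed              +0.21 +- 0.15    +0.20  1.000
lambda:conifer_seed            +0.21 +- 0.11    +0.27  1.000
lambda:site[AVs]:fagus_seed    +0.39 +- 0.22    +0.73  1.000
p:intercept                    -0.17 +- 0.19    -1.08  1.008
...
flagged parameters (rhat >= 1.1): ['tau', 'sigma_eps']
```

Reading this: `lambda:` rows are abundance effects on log density per SD of
the covariate — here the beech-seed effect is recovered almost exactly
(+0.21 vs +0.20), and the avalanche site is estimated far below the
managed-forest reference. The intercept pair (`lambda:intercept`,
`p:intercept`) sits several SDs from the truth *with all chains agreeing*:
on a single dataset the split between "how many animals" and "how
detectable" is weakly identified, a well-known N-mixture property. That is
why the package judges the estimator by interval coverage across 20
replicate studies (where these parameters reach nominal coverage, see
`examples/05_parameter_recovery.py`), not by one fit. The flagged τ/σ_ε
show the random-effect precision mixing slowly on this dataset — the other
rows are safe to read.

The other examples cover simulation (`01`), goodness-of-fit (`03`,
printing a Bayesian p-value and c-hat for the fitted model),
marginal-effect curves by site (`04`, showing the open avalanche site
converging towards the canopy sites as beech seed rain grows), and
parameter recovery (`05`).

## Command line

A thin CLI wraps the same library calls:

```sh
mastmix simulate -o run/data --seed 4           # synthetic study + truth
mastmix fit      -c config.yaml                 # MCMC + convergence report
mastmix check    -c config.yaml                 # posterior-predictive GOF
mastmix report   -c config.yaml                 # coefficient table + curves
mastmix recover  -o run/recovery --seed 1       # recovery experiment
```

`config.yaml` names the data directory, output directory, taxon, reference
site and the MCMC block; every output directory carries a JSON sidecar
with the resolved configuration and seeds. `fit` exits nonzero when any
R-hat ≥ 1.1 unless `--allow-unconverged` is given.

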