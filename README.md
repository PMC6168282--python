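# urbanwild

Statistical analysis of camera-trap surveys of mammal communities along
urban–wild development gradients: from raw photo records to detection
histories, Hill-number diversity, Bayesian detection-rate models, a
multivariate-Bernoulli multispecies occupancy model, posterior-predictive
fit checks, and cross-study occupancy comparisons. A synthetic survey
generator with known ground truth makes the entire chain testable without
any field data.

## Who this is for

Ecologists and biostatisticians analysing stratified camera-trap surveys —
sites classified into development levels by housing density (urban,
suburban, exurban, rural, wild) and local plot types (large forest, small
forest fragment, open area, residential yard) — who want the full
occupancy/relative-abundance workflow in reusable, tested Python.

## The models

**Independent sequences.** Consecutive photos of one species at one site
are merged into a single detection event whenever inter-photo gaps are
strictly under 60 s. Sequences per camera-night give the detection rate
(a relative-abundance index); collapsing sequences to daily
detection/non-detection gives the occupancy data.

**Multispecies occupancy.** The latent presence vector Z of S species at a
site follows a multivariate Bernoulli with one probability per joint
state — for two species, Z ~ MVB(ψ₁₁, ψ₁₀, ψ₀₁, ψ₀₀). Cells are built from
log-linear natural parameters: per-species terms f_s = x'β_s (logit-linear
in mean-centered site covariates) and pairwise interaction terms f_st, via
a softmax over the 2^S states. f_st = 0 recovers exact independence, the
default assumption. Conditional on presence, daily detections are
Bernoulli(p) with a logit-linear detection model; an optional site-level
normal random intercept on the detection logit (marginalized by
Gauss–Hermite quadrature) absorbs extra site heterogeneity. Priors are
weakly-informative logistic; covariates with pairwise Pearson correlation
above 0.60 receive the restrictive logistic(0, 1) shrinkage prior.
Posteriors are sampled with independently seeded ensemble MCMC chains,
gated on split-chain R̂ ≤ 1.1. Predictors are "significant" when their 95%
credible interval excludes zero.

**Detection-rate models.** Site counts of independent sequences are
Poisson with a log link and log camera-nights offset, so exp(β) is a rate
per day; a cell-means design compares strata and a covariate design
evaluates per-species predictors.

**Diversity.** Hill numbers of order q = 0 (richness) and q = 1
(exponential Shannon entropy) from incidence frequencies per stratum, with
incidence rarefaction, Chao2-asymptote extrapolation, and seeded bootstrap
confidence intervals. A weighted quadratic curve locates the diversity
peak along the ordered gradient.

**Fit checking.** Posterior-predictive checks with the sum of squared
Pearson residuals: p_B = Pr(T(y_sim) > T(y)); fit is adequate when
0.1 < p_B < 0.9.

**Community comparison.** Marginal-occupancy distributions are summarized
as Tukey five-number boxes; two groups differ significantly only when
their interquartile ranges are disjoint.

## Worked example

`examples/demo_pipeline.yaml` synthesizes a three-species survey over 72
camera sites (4 per available stratum cell, 21-day deployments) and runs
every stage:

```sh
urbanwild run-all --config examples/demo_pipeline.yaml
```

prints (seed 11):

```json
{
  "naive_occupancy": {"mean": 0.606, "min": 0.403, "max": 0.75},
  "diversity_peak_level": "suburban",
  "rate_rhat_max": 1.087,
  "rate_peak_level": "urban",
  "count_ppc_p_b": 0.867,
  "count_ppc_adequate": true,
  "occupancy_rhat_max": 1.038,
  "occupancy_ppc_p_b": 0.375,
  "occupancy_ppc_adequate": true
}
```

Reading the output: `naive_occupancy` is the raw fraction of sites with at
least one detection (mean/min/max across species, uncorrected for
imperfect detection); the Shannon-diversity trend curve peaks at the
suburban level of this synthetic gradient; both MCMC fits pass the
R̂ ≤ 1.1 convergence gate; and both posterior-predictive p-values fall
inside the (0.1, 0.9) adequacy window, as they should when the fitted
model matches the generating process. The run writes tidy CSVs (sequences,
rates, diversity estimates, posterior draws and summaries, marginal
occupancy per stratum) plus `manifest.json`; rerunning with the same seed
and config reproduces every output byte-for-byte.

The same stages are available individually (`urbanwild simulate`,
`collapse`, `rates`, `validate`, `compare`) and as library functions
(`urbanwild.data`, `.simulate`, `.diversity`, `.occupancy`, `.counts`,
`.diagnostics`, `.compare`, `.pipeline`).

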