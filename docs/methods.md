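# Methods

This note documents the statistical machinery, the conventions the package
fixes where the field leaves choices open, and what the synthetic test bed
does and does not demonstrate.

## Data reductions

**Independent sequences.** Photos of the same species at the same site are
merged while successive gaps are *strictly* less than 60 s (the
`gap_seconds` parameter; units seconds, default 60). The rule is applied
after a stable sort by (site, species, timestamp), chains transitively
(gaps of 59 s merge indefinitely), and is idempotent: in the output every
surviving gap is ≥ 60 s, so re-collapsing changes nothing. A sequence
keeps its first photo's timestamp and the maximum simultaneous animal
count — the maximum, rather than a sum over photos, because the same
individuals typically appear in every frame of a burst and summing would
double-count them.

**Development levels.** Housing density (houses/km²) is classified with
the Silvis-style bins. The published bin edges do not tile the line
(0.5–0.51, 12.63–12.64, 147.047–147.048, and the point 1000), so the
package closes the gaps half-open: wild [0, 0.5), rural [0.5, 12.64),
exurban [12.64, 147.048), suburban [147.048, 1000], urban (1000, ∞).
Densities inside a printed gap therefore fall in the higher-numbered bin's
lower neighbour deterministically (e.g. 147.0475 → exurban).

**Camera-nights and days.** A camera-night is one calendar day with the
effort mask set; partial first/last days count as full nights. Day
boundaries are local midnight; day *d* of a site is the *d*-th calendar
day of its deployment. Detection rate is detections ÷ camera-nights,
exactly. Multi-individual sequences count once by default; the
`per_animal` flag weights each sequence by its animal count instead.

## Multispecies occupancy model

The joint latent state of S species at site *i* is multivariate Bernoulli.
The package parameterizes the 2^S cell probabilities log-linearly:

    P(Z = z) ∝ exp( Σ_s z_s f_si + Σ_{s<t} z_s z_t f_st ),
    f_si = x_i' β_s   (occupancy design, logit scale)

The softmax guarantees a valid probability vector at any parameter value;
with all pairwise terms f_st = 0 the cells factorize exactly into
independent Bernoullis with ψ_s = logit⁻¹(f_s), and the joint likelihood
equals the product of single-species occupancy likelihoods (this
reduction is verified to 1e-12 in the tests). Interactions are an exposed
switch (`estimate_interactions`), off by default: the species are then
fitted jointly but independently.

Detection is Bernoulli per occasion conditional on presence, with p
constant across occasions within a deployment and logit-linear in
site-level detection covariates. The site likelihood marginalizes the
latent state:

    L_i = Σ_z P(Z = z) Π_s [ z_s = 1 : p^d (1-p)^(k-d) ;
                             z_s = 0 : 1{d_s = 0} ]

computed on the log scale via logsumexp; a species detected at a site
contributes exactly zero to every state marking it absent. The optimized
implementation works on sufficient statistics (detections d, nights k per
site and species); the generic `site_likelihood` accepts per-occasion p
and an effort mask and is cross-checked against brute-force 2^S
enumeration.

**Random detection effect.** A site-level normal intercept u_i ~ N(0, σ²)
on the detection logit (the structure used for coyote in the motivating
analysis, whose fit is otherwise inadequate) is marginalized inside the
likelihood by 20-node Gauss–Hermite quadrature rather than sampled
per-site; σ gets a half-normal(1) prior via a log transform with Jacobian.
Twenty nodes are ample for a one-dimensional logit-normal integral at the
σ ≲ 2 values the prior supports.

**Priors.** Coefficients get logistic(0, √10) by default — heavy-tailed
and weakly informative on the logit scale. Any design column whose
pairwise Pearson correlation with another column exceeds 0.60 receives the
restrictive logistic(0, 1) shrinkage prior instead (ridge-like), the
convention used when collinear covariates such as road and housing density
must coexist. Designs are mean-centered (enforced to |mean| < 1e-10) and
rank-checked; duplicated columns abort the fit.

**Sampling.** Affine-invariant ensemble MCMC (emcee). Each requested
chain — two by default for occupancy, three for count models — is an
independently seeded ensemble whose post-warmup draws are flattened and
thinned to ≤1000 per chain. Convergence is gated on split-chain
Gelman–Rubin R̂ ≤ 1.1 computed across the chains; parameters failing the
gate are flagged and never reported significant. Count-model walkers are
initialized at the closed-form per-stratum rate MLE, which removes the
slow warmup a far-from-mass origin start produces in cell-means designs.
A NaN posterior density aborts with the offending parameter named.

**Marginal occupancy.** Per stratum (development level × plot type, and
optionally city), per-draw marginal ψ — for pairs, the sum of all joint
states containing the species, e.g. ψ₁₁ + ψ₁₀ — is averaged over the
stratum's sites and summarized by the posterior mean and central 95%
interval. Unsampled strata (yards in urban or wild) are absent from the
output, never extrapolated.

## Detection-rate (count) models

Counts of independent sequences per site are Poisson with log link and a
log camera-nights offset (the model reads "count/day" but fits counts;
the offset is the standard reconciliation). Cell-means stratum designs
give per-stratum rates directly as exp(β); covariate designs are
mean-centered and share the occupancy prior rules and significance
convention. Overdispersion is deliberately not modeled by default — the
posterior-predictive check arbitrates adequacy — but a negative-binomial
switch (log-dispersion parameter, logistic(0, 2) prior) exists.

## Diversity

Incidence frequencies Q_i (number of sites where species *i* was detected
out of T) feed Hill numbers:

- q = 0: observed richness at the observed size; interpolation by the
  standard incidence rarefaction expectation
  S(t) = S_obs − Σ_i C(T−Q_i, t)/C(T, t); extrapolation approaches the
  Chao2 asymptote S_obs + (T−1)/T · Q₁²/(2Q₂) (or the bias-corrected
  Q₁(Q₁−1)/2 form when no doubletons exist).
- q = 1: exp(−Σ π_i ln π_i) with π_i = Q_i/ΣQ_j, no bias correction, at
  the observed size; smaller sizes by seeded hypergeometric Monte-Carlo
  subsampling of sampling units (the expected entropy under subsampling
  has no closed form). q = 1 does not extrapolate beyond T. Display on
  the log scale (ln of the Hill number = Shannon entropy) is left to the
  caller.

**Confidence intervals** come from a seeded bootstrap over sampling
units: incidence counts are resampled as Binomial(T, Q_i/T), the
estimator recomputed B times (default 200, minimum 50), and a
normal-approximation interval (estimate ± z·SE_boot) returned. The
normal form was chosen over the percentile form because the plug-in
Shannon–Hill estimator's bias leaves percentile intervals noticeably
below nominal coverage in simulation; the normal interval achieves ≈92%
empirical coverage at T = 120 in the test suite's simulation study.
Intervals are clamped to bracket the point estimate and floored at 1
(one species is the minimum effective number). This bootstrap ignores
never-detected species, so the richness interval is conditional on the
observed species pool.

**Gradient trend.** The "smooth curve with a polynomial term" across the
five ordered levels is realized as a weighted quadratic least-squares fit
(weights = inverse interval variance, intervals read as ±1.96 SE): with
at most five points a richer additive model is unidentifiable, and the
curve is used only for display and for locating the peak level (argmax of
the fitted values over sampled levels).

## Posterior-predictive checks

The discrepancy is the sum of squared Pearson residuals. For counts,
T = Σ (y−μ)²/μ with μ the per-draw fitted mean. For occupancy histories,
each surveyed site-occasion cell contributes (y−μ)²/(μ(1−μ)) where μ is
the per-draw detection probability of that cell; two conditionings are
implemented because the derivation the original analysis cites is in an
unavailable supplement: the default *marginal* μ = ψp, and a *latent*
variant μ = z·p with z drawn from its posterior conditional given the
observed history. Cells with degenerate variance (μ exactly 0 or 1) are
skipped with a log entry. Replicate data re-simulate latent states and
detections from the same draw. The Bayesian p-value is
p_B = Pr(T_sim > T_obs) over matched draws, with adequacy declared iff
0.1 < p_B < 0.9; both conditionings pass the calibration experiment
(adequate fit in ≥80% of surveys simulated from the fitted model's own
structure), and neither is claimed to reproduce the original derivation.

R̂ is the standard split-chain potential scale reduction; it requires at
least two chains, returns 1.0 exactly for constant chains, and gates at
1.1 throughout.

## Community comparison

Box summaries use Tukey hinges (medians of the lower/upper halves,
including the overall median when n is odd): this median-inclusive
convention reproduces the worked quartiles the comparison rule expects
(e.g. [0.1, 0.2, 0.3, 0.4] → hinges 0.15/0.35) and is verified against a
brute-force order-statistic oracle. Whiskers extend to the most extreme
values within 1.5 IQR. Two distributions differ significantly iff their
closed [q1, q3] intervals are disjoint; boxes touching at a point
overlap. External multi-study tables (species, study, occupancy,
diet_class) are averaged unweighted per species, optionally after
dropping omnivore rows; the global comparison table itself is
user-supplied, not bundled.

## Synthetic surveys

The generator produces exactly the structure the models assume: sites
stratified over the five density-defined levels and four plot types (no
yards in urban or wild strata), housing densities drawn within each
level's bin, 21-day deployments (the three-week field protocol),
continuous covariates as standard normals plus Bernoulli indicators, an
optional correlated covariate pair (default scenario knob 0.87, the
road/housing collinearity that motivates the restrictive prior), latent
states drawn from the log-linear MVB cells, daily Bernoulli detections
where present, and Poisson event streams expanded into photo bursts with
intra-burst gaps < 60 s and inter-event gaps > 60 s so the collapsing
rule recovers event counts exactly. A fixed seed yields byte-identical
output end-to-end.

What it does not emulate — and hence what green tests do not show about
field data: spatial autocorrelation among sites, animal movement and
home-range structure, seasonal detection trends beyond supplied
covariates, misidentified species, camera failures inside deployments
(the effort mask machinery supports them; the generator does not create
them), and non-Poisson clumping of visits beyond the burst process.

## Problem sizes and numerical choices

Simulation experiments in the test and acceptance suites use 150–1000
sites with 10–21 occasions and 10–50 replicates — sizes at which the
checked properties (3-SD recovery, ≤5% type-I rate, ≥80% PPC calibration)
are comfortably resolved by the Monte-Carlo error of the experiment; the
acceptance script's bundled community uses 144 sites across the full
stratification. MCMC defaults (warmup 300–400, 300–400 retained ensemble
steps, 8–14 walkers) give R̂ well under 1.1 on these posteriors of ≤10
parameters. Likelihoods and cell probabilities are computed on the log
scale throughout (no overflow at |f| = 800); likelihood equality checks
use 1e-12 absolute tolerance; design-centering is enforced at 1e-10;
bootstrap and MCMC randomness is always explicitly seeded, with stage
seeds derived from the pipeline seed by hashing so stages are
independently reproducible.

## Known limitations

- Detection probability is occasion-constant within a deployment;
  occasion-varying detection designs would need the generic likelihood
  path, which is present but not wired into the sampler.
- Interaction terms are scalar per species pair (no covariate-dependent
  co-occurrence), and third- and higher-order interactions are out of
  scope.
- The ensemble sampler is adequate for the ≤ dozens-of-parameters designs
  used here; very large covariate rosters with city interactions would
  warrant a gradient-based sampler.
- The diversity bootstrap conditions on the observed species pool and
  does not propagate uncertainty in the number of never-detected species
  into the q = 1 interval.
- Single-season (static) occupancy only; no spatial or temporal
  autocorrelation.
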