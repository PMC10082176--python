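# Methods

## The scientific setting

`traitselect` analyzes how local plant species richness reshapes functional
trait distributions in wetland communities — both *where* the distribution
sits (selection directionality, the mean) and *how wide* it is (selection
intensity, the dispersion) — and how, within species, those shifts relate
to demographic performance measured as population density.  The design it
models is a replicated richness gradient: 4 wetland ecosystems ordered by
soil fertility (bog, fen, wet meadow, fluvial marsh), 8 communities per
ecosystem (7 in the wet meadow; 31 in total) of ~20–25 m² spanning 2–16
species, 80 ramets sampled per community over 2 campaigns, 7 leaf traits
per ramet, and a point–plant distance per ramet for density estimation.

## Distributional models

Each trait is modeled with a two-parameter response whose mean and
dispersion both carry linear predictors (a "distributional" or
location–scale regression — a GLM's fixed-dispersion assumption is exactly
what the science must relax):

* positive traits (leaf angle, extended length EL, leaf area LA, SLA,
  chlorophyll content, flavonoid index): Gamma with mean μ and dispersion
  σ, parameterized as shape `1/σ²`, scale `μσ²`, so `E[y] = μ` and σ is the
  coefficient of variation.  σ's algebraic definition is a package choice
  (`convention="cv"`, the location–scale–shape convention); the alternative
  `σ = 1/shape` is available behind a flag.  Links: log on both μ and σ.
* LDMC, a (0,1) mass fraction: Beta with mean μ (logit link) and precision
  ϕ (log link), `a = μϕ`, `b = (1−μ)ϕ`, `Var = μ(1−μ)/(1+ϕ)`.

With these links an exponentiated slope is a multiplicative effect per
added species.  Because larger ϕ means *less* dispersion, exponentiated
ϕ-slopes are inverted at reporting time so that a value below 1 always
reads "the distribution narrows" for every family.

### Community level

The fullest community model gives both sides campaign intercepts, fixed
sum-to-zero ecosystem deviations, hierarchical community deviations
(normal, estimated SD), and one richness slope per ecosystem:

    g1(μ_i) = β0 + β_T2 + β_Ee + β_Cc + β1_Ee · D_c
    g2(σ_i) = γ0 + γ_T2 + γ_Ee + γ_Cc + γ1_Ee · D_c

The candidate set crosses the two slope terms: `M_com0` (neither),
`M_com1` (mean only), `M_com2` (dispersion only), `M_com3` (both), plus
`M_com3p`, which refits `M_com3` to a counterfactual dataset in which each
individual's value is replaced by its fitted species mean (campaign
intercepts + hierarchical species intercept), removing intraspecific trait
variation (ITV) while preserving species composition.

### Species level

Species-level models act on *focal* species — those occurring in ≥ 4
communities of their ecosystem and at both extremes of its richness
gradient — and add per-species deviations and, depending on the variant,
per-species richness slopes on either side (`M_sp0` … `M_sp3` crossing
ecosystem-level vs species-level slopes on μ and σ).  All per-species terms
are jointly multinormal with an estimated covariance (half-normal SDs,
LKJ(2) correlation).

Two modeling choices here are the package's own:

* the species-block richness covariate is centered at its sample mean, so a
  species "deviation" is its offset in an average-richness community.  Raw
  richness makes deviation and slope ~99% collinear, which is statistically
  equivalent but computationally hostile; slopes — the only quantity any
  downstream analysis uses — are identical under either convention.
* ecosystem deviations are fixed effects (only community terms are
  described as hierarchical); with 4 ecosystems a hierarchical SD would be
  essentially unidentified anyway.

### Density model

Species demographic performance is per-(species, community) density
(ind m⁻², campaign-pooled), modeled with the species-level structure
(Gamma family, no campaign term, per-species slopes on both sides).  The
μ-side species slope is the demographic response to richness.

## Point–plant density

Community density is `dens = 10⁴ / mean(d_cm)²` with d the point-to-nearest-
plant distances in cm — the only dimensionally consistent reading of the
protocol (a literal variant is kept behind `eq1_variant="literal"` for
audit).  For a homogeneous Poisson pattern of intensity λ the nearest
distance is Rayleigh with `E[d] = 1/(2√λ)`, so this estimator is 4× the
Poisson-consistent one; closest-individual estimators are biased upward and
no bias correction is applied — the estimate is used comparatively along
the gradient, where a constant factor cancels.  Species densities are
apportioned from the community estimate by sampled count fractions, so they
sum exactly to the community value.

## Inference

Posteriors are sampled with the package's own No-U-Turn sampler
(slice-variant dynamic trajectories, dual-averaging step size targeting
0.9 acceptance, diagonal mass matrix adapted in a mid-warmup window),
driven by fully analytic gradients of the joint log-posterior.  Design
choices that matter:

* non-centered parameterization for all hierarchical terms; log-transformed
  SDs with half-normal(1) priors; normal(0, 2.5) on fixed link-scale
  coefficients; LKJ(2) on the species-block correlation via the canonical
  partial-correlation (tanh) transform.  The data-side gradient flows
  analytically through the block's Cholesky factor; the tiny u → C map and
  its prior (≤ 6 scalars) are differentiated by vectorized central
  differences of closed-form expressions (error ~1e-9, verified against
  full finite differences in the tests).
* fixed-effect design columns are centered internally during sampling and
  the intercept is shifted back at reporting time, as mainstream samplers
  do; the raw-richness interpretation of slopes is untouched.
* defaults: 4 chains × 1000 warmup + 1000 retained draws; tests and the
  reproduction script use fewer chains/draws (stated per experiment) to
  keep replicate studies compact.  Initialization is jittered zeros on the
  link scale; every fit takes an explicit seed and identical (model, data,
  config, seed) reproduce byte-identical draws.
* diagnostics: split-R̂ (cross-checked against arviz), a bulk effective
  sample size via Geyer's initial monotone sequence, divergence counts.
  Results breaching R̂ > 1.01 or the divergence cap are tagged not-ok and
  warned about, never silently returned.

A slope is **substantial** when the 90% equal-tailed credible interval of
its exponentiated value excludes 1 (raw-scale intervals are reported
alongside).  Posterior-predictive checks simulate replicate datasets from
thinned draws and report each community's rank of an observed statistic
(mean, CV, 5%/95% quantiles).

## Model comparison

PSIS-LOO is implemented natively: per observation, importance ratios
`1/p(y_i|θ_s)`; the largest ~20% replaced by expected order statistics of a
generalized Pareto fitted to the tail exceedances (Zhang–Stephens
empirical-Bayes fit with the standard weak prior on the shape k̂); weights
truncated at `S^{3/4}·w̄`; k̂ > 0.7 flagged.  Stacking weights maximize the
pooled leave-one-out log predictive density of the model mixture over the
simplex (concave; SLSQP from the uniform start with analytic gradient, so
ties give exactly uniform weights and the optimum is deterministic).  Ties
for "best model" break toward fewer slope terms.  arviz's PSIS-LOO is used
in the tests as an independent cross-check (agreement < 0.003 per
observation), never as the implementation.

The no-ITV refit `M_com3p` is scored against the species-mean response it
was fitted to; scoring all models against the observed individual data is
available as a documented alternative, since either convention is
defensible and they answer slightly different questions.

## Strategy classification

A focal species is **Master-of-some** when its density μ-slope is
substantial and below 1 (it dominates species-poor communities and declines
as richness rises) and **Jack-of-all-trades** otherwise; the trait-variation
sign table travels with the call but does not affect the label, which is
the operational reading of the sign-table convention (a species with stable
density and *no* detected trait variation is still a Jack).  A substantial
density *increase* has no name in the framework and is mapped to Jack with
`density_class="Increase"` plus a warning.  The dispersion–density
covariation report gives the Pearson correlation between species'
exponentiated trait-dispersion slopes and density μ-slopes (posterior
medians; a draw-wise correlation distribution with a 90% interval is
available by pairing draws across species).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis assumes:
the 4×8(−1) community scaffold with per-ecosystem richness gradients,
areas ~U(20, 25) m², 80 ramets per community split 40/40 across campaigns
and 20/20 across two harvesters (an even split; harvesters have no
generative effect), species pools with ~3 persistent core species per
ecosystem plus geometrically-weighted occasional species, within-community
relative abundances from a symmetric Dirichlet (concentration 0.6, largest
shares assigned to core species — monodominance at low richness), traits
drawn from exactly the hierarchical distributional models above, distances
from a homogeneous Poisson pattern (intensity default 200 ind m⁻²,
plausible for dense wetland ramet mats) on a toroidal square plot (side
√area; wrap avoids edge bias), and flowering flags as Bernoulli(0.079)
purely to exercise I/O.  Per-ecosystem gradient minima alternate 2/3 so
that ~10–11 species pass the focal rule, as in the emulated design.

It does **not** emulate: real species identities or trait magnitudes beyond
plausible ranges, spatial clustering or species-specific point patterns,
campaign-by-trait phenology, measurement error in the instruments, or
soil-chemistry covariates.  Passing tests therefore demonstrate that the
*machinery* recovers what it assumes — not that any ecological conclusion
holds in real wetlands.  Shipped parameter presets ("bog-like",
"marsh-like") are package fixtures, not field estimates.

## Validation experiments

`traitselect.experiments` runs the package against its own generative
truth; tests and `scripts/acceptance.py` call these with stated sizes:

* **coverage** — refitting the full community model to its own simulations
  (2 ecosystems × 4 communities × 30 individuals, μ-slope log 1.06,
  σ-slope log 1.03, 20 replicates): 90% intervals should cover the truth at
  the nominal rate (binomial test at α = 0.01).
* **exact-LOO oracle** — PSIS-LOO vs 20 brute-force refits on a toy Gamma
  intercept model, per-observation agreement within 0.1.  Draw counts are
  chosen so Monte-Carlo noise (which affects the exact refit estimate as
  much as PSIS) stays inside that band; at a few hundred draws the noise
  alone exceeds it.
* **model selection** — data simulated with both slopes at the full design
  scale should hand the largest stacking weight to the full model; null
  data (no slopes, 10 reduced replicates) should leave the intercept model
  non-dominated.
* **strategy** — species simulated with density slope exp = 0.8 vs 1.0
  across a 16-community gradient are labeled Master vs Jack in ≥ 90% of
  replicate fits.

## Numerical details and edge cases

* (0,1) responses are clamped to [1e-4, 1−1e-4] before Beta fitting; the
  clamp count is logged and carried on the model spec.
* A hierarchical deviation with a single level is dropped (absorbed by the
  intercept and unidentifiable against its own SD).
* Empty distance vectors, non-positive distances, λ ≤ 0, richness outside
  [2, 16] (strict mode), unknown models/traits and missing fits are
  rejected with specific errors; CSV validation reports 1-based line
  numbers and rejects unparseable or domain-violating rows.
* Stacking tolerances: simplex feasibility to 1e-8, objective tolerance
  1e-14; degenerate (zero-variance) covariation inputs return an explicit
  degenerate flag rather than NaN surprises.

## Known limitations

* The sampler is single-threaded and adapts only a diagonal metric; very
  small, weakly identified models (e.g. the density model on few species ×
  few communities) can need deep trajectories.  Tests cap tree depth there
  and tolerate the cost.
* Split-R̂ is the classic (non rank-normalized) form.
* The point–plant estimator's finite-sample and clustering biases are
  documented, not corrected.
* The species-mean model used for the no-ITV counterfactual pools
  ecosystems (campaign + species intercepts only), matching its stated
  structure; it is not meant for inference on its own.
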