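# traitselect

Hierarchical Bayesian analysis of how local plant species richness reshapes
functional-trait distributions — and what that costs species demographically.

## The problem

Along a within-ecosystem species-richness gradient, biotic selection can
act on a trait distribution in two separable ways: it can *displace* the
distribution (selection directionality, a shift of the mean μ) and it can
*narrow or widen* it (selection intensity, a change of the dispersion σ or
precision ϕ).  Ordinary GLMs force a fixed dispersion and cannot separate
the two.  `traitselect` implements the full distributional-regression
workflow for a replicated wetland richness gradient (4 ecosystems ×
8 communities spanning 2–16 species, 80 ramets per community, 7 leaf
traits), from raw point–plant distances to demographic-strategy labels:

1. **synthetic data** — a generative twin of the study design (species
   pools, Dirichlet abundances, the trait models below, a Poisson spatial
   pattern for distances), so the whole pipeline is testable end to end;
2. **density** — the point–plant estimator `dens = 10⁴ / mean(d_cm)²`
   (ind m⁻²) with count-proportional species apportionment;
3. **models** — Gamma(μ, σ) and Beta(μ, ϕ) distributional regressions in
   which *both* parameters get campaign intercepts, ecosystem deviations,
   hierarchical community deviations and richness slopes, at the community
   level (`M_com0`–`M_com3`, plus the no-ITV refit `M_com3'`) and at the
   species level with a correlated multinormal species block
   (`M_sp0`–`M_sp3`, and a density model with the same structure);
4. **inference** — a native No-U-Turn sampler with analytic gradients;
   split-R̂/ESS/divergence diagnostics; a slope is *substantial* when the
   90% credible interval of its exponentiated value excludes 1;
5. **comparison** — native PSIS-LOO (generalized-Pareto tail smoothing)
   and stacking weights maximizing the leave-one-out predictive density;
6. **strategy** — species whose density declines substantially with
   richness are *Master-of-some*, species holding density are
   *Jack-of-all-trades*, with a trait-variation sign table and the
   dispersion–density covariation report.

See `docs/methods.md` for the model equations, priors, parameterizations
and the design decisions behind them.

## A worked example

Simulate a reduced design, estimate densities, fit the full community
model for extended leaf length (EL), and read off the richness effects:

```python
import traitselect as ts
from traitselect.experiments import reduced_design_config

cfg = reduced_design_config()            # 2 ecosystems x 4 communities x 30
design = ts.make_design(cfg, seed=3)
params = ts.preset_parameters(ecosystems=("bog", "fen"))
recs = ts.simulate_traits(design, params, seed=4)
recs = ts.simulate_point_plant_distances(recs, design, intensity=200, seed=5)

print(ts.estimate_density(recs.loc[recs.community == "bog_c1", "distance_cm"]))

spec = ts.build("M_com3", "EL", recs)
res = ts.fit(spec, ts.SamplerConfig(chains=2, warmup=400, samples=400), seed=7)
for ss in ts.substantiality(res, "mu:beta1_E"):
    print(ss.parameter, round(ss.exp_median, 3), (round(ss.ci_low, 3),
          round(ss.ci_high, 3)), "substantial" if ss.substantial else "-")
```

Output:

```
DensityEstimate(community_id=None, species=None, n=30, dens=992.9061372089224, mean_distance_cm=3.1735540726676366)
mu:beta1_E[bog] 0.975 (0.949, 1.005) -
mu:beta1_E[fen] 1.021 (0.991, 1.052) -
```

The density estimate (~993 ind m⁻² from a mean distance of 3.17 cm) is the
closest-individual reading of the 30 point–plant distances in that
community; the generative intensity was 200 ind m⁻², and the gap is the
estimator's documented upward bias (it is 4× the Poisson-consistent
estimator, and 30 distances carry large sampling noise) — it is used
comparatively along the gradient, where constant factors cancel.  Each slope line is the multiplicative change of mean EL per
added species in that ecosystem with its 90% credible interval: both
intervals include 1 here, so at this reduced scale no directional effect
is declared — the generating slope (×1.02) is small, and the
coverage/selection experiments in `tests/test_acceptance.py` show exactly
when it becomes detectable.

The same workflow from a shell:

```bash
traitselect simulate --seed 42 --out data/
traitselect density --in data/records.csv --by community,species --out density.csv
traitselect run --config pipeline.yaml --out results/
```

`traitselect run` executes simulate → density → fit → compare → classify
and writes the stacking-weight table, slope-interval tables, the
strategy/sign table, the covariation report, diagnostics and a manifest
with every seed.

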