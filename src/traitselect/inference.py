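"""Posterior sampling, convergence diagnostics and slope substantiality.

``fit`` samples a :class:`~traitselect.model_builder.TraitModelSpec` with
the package's No-U-Turn sampler (4 independent chains by default), returns
all draws on the constrained scale together with the per-observation
log-likelihood matrix needed for leave-one-out model comparison, and runs
split-R̂ / effective-sample-size / divergence diagnostics.  Results whose
R̂ exceeds 1.01 or whose divergence count exceeds the configured cap are
tagged ``ok=False`` and a warning is emitted — they are never silently
returned as clean.

A slope is *substantial* when the 90% equal-tailed credible interval of its
exponentiated value excludes 1; for Beta precision slopes the exponentiated
value is inverted first so that values below 1 always read "dispersion
shrinks" (precision is inverse dispersion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._posterior import ParamLayout
from .model_builder import TraitModelSpec, build
from .nuts import NutsConfig, sample_nuts

__all__ = [
    "SamplerConfig",
    "PosteriorResult",
    "SlopeSummary",
    "fit",
    "substantiality",
    "posterior_predictive_check",
    "fit_species_mean_model",
    "split_rhat",
    "effective_sample_size",
]


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    divergence_cap: int = 20
    rhat_threshold: float = 1.01


@dataclass
class PosteriorResult:
    spec: TraitModelSpec
    draws: np.ndarray               # (chains, samples, n_params) constrained
    param_names: list[str]
    loglik: np.ndarray              # (chains*samples, n_obs)
    unconstrained: np.ndarray       # (chains, samples, dim)
    rhat: dict[str, float]
    ess: dict[str, float]
    divergences: int
    mean_accept: float
    seed: int
    sampler_config: SamplerConfig
    ok: bool = True
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        try:
            j = self.param_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}")
        return self.draws[:, :, j].reshape(-1)

    def names_matching(self, prefix: str) -> list[str]:
        return [nm for nm in self.param_names if nm.startswith(prefix)]

    def diagnostics_dict(self) -> dict:
        return dict(
            ok=self.ok,
            divergences=self.divergences,
            mean_accept=self.mean_accept,
            max_rhat=float(max(self.rhat.values())),
            min_ess=float(min(self.ess.values())),
            warnings=self.warnings_,
            seed=self.seed,
            model=self.spec.name,
            trait=self.spec.trait,
        )

    def draws_frame(self) -> pd.DataFrame:
        c, s, p = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * s, p), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(c), s))
        df.insert(1, "iteration", np.tile(np.arange(s), c))
        return df


@dataclass(frozen=True)
class SlopeSummary:
    parameter: str
    exp_median: float
    ci_low: float
    ci_high: float
    substantial: bool
    sign: int                      # +1 / -1 / 0
    raw_ci_low: float
    raw_ci_high: float
    level: float = 0.90


def split_rhat(x: np.ndarray) -> float:
    """Split-R̂ of draws shaped (chains, samples)."""
    c, s = x.shape
    half = s // 2
    if half < 2:
        return np.nan
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = splits.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(x: np.ndarray) -> float:
    """Bulk ESS via Geyer's initial monotone positive sequence."""
    c, s = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    if np.allclose(x, 0):
        return float(c * s)
    nfft = int(2 ** np.ceil(np.log2(2 * s)))
    acov = np.fft.irfft(np.abs(np.fft.rfft(x, n=nfft, axis=1)) ** 2, axis=1)[:, :s]
    acov = acov / s
    var = acov[:, 0].mean()
    if var == 0:
        return float(c * s)
    rho = acov.mean(axis=0) / var
    # pair sums, initial monotone positive sequence
    t = 1
    rho_sum = 0.0
    prev = np.inf
    while t + 1 < s:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        rho_sum += pair
        t += 2
    ess = c * s / (1.0 + 2.0 * rho_sum)
    return float(min(max(ess, 1.0), c * s))


def fit(
    spec: TraitModelSpec,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorResult:
    """Sample the posterior of a model specification.

    Chains get independent, reproducible substreams of ``seed``; identical
    (spec, config, seed) yields identical draw tensors.
    """
    cfg = sampler_config or SamplerConfig()
    layout = ParamLayout(spec)
    nuts_cfg = NutsConfig(
        warmup=cfg.warmup,
        samples=cfg.samples,
        target_accept=cfg.target_accept,
        max_treedepth=cfg.max_treedepth,
    )
    seeds = np.random.SeedSequence(seed).spawn(cfg.chains)
    chain_draws = []
    divergences = 0
    accepts = []
    for ch in range(cfg.chains):
        rng = np.random.default_rng(seeds[ch])
        theta0 = 0.1 * rng.uniform(-1.0, 1.0, size=layout.dim)
        lp0, _ = layout.logp_and_grad(theta0)
        if not np.isfinite(lp0):
            ll = layout.pointwise_loglik(theta0)
            bad = int(np.flatnonzero(~np.isfinite(ll))[0]) if np.any(~np.isfinite(ll)) else -1
            raise ValueError(
                f"non-finite log-density at initialization (first offending row: {bad})"
            )
        res = sample_nuts(layout.logp_and_grad, theta0, nuts_cfg, rng)
        chain_draws.append(res.draws)
        divergences += res.divergences
        accepts.append(res.mean_accept)
    unconstrained = np.stack(chain_draws)  # (chains, samples, dim)

    names = layout.constrained_names()
    c, s, _ = unconstrained.shape
    constrained = np.empty((c, s, len(names)))
    loglik = np.empty((c * s, spec.n_obs))
    k = 0
    for i in range(c):
        for j in range(s):
            theta = unconstrained[i, j]
            constrained[i, j] = layout.constrain(theta)
            loglik[k] = layout.pointwise_loglik(theta)
            k += 1

    rhat = {nm: split_rhat(constrained[:, :, p]) for p, nm in enumerate(names)}
    ess = {nm: effective_sample_size(constrained[:, :, p]) for p, nm in enumerate(names)}
    msgs = []
    finite_rhat = [v for v in rhat.values() if np.isfinite(v)]
    if finite_rhat and max(finite_rhat) > cfg.rhat_threshold:
        worst = max((v, k_) for k_, v in rhat.items() if np.isfinite(v))
        msgs.append(f"split-Rhat {worst[0]:.3f} for {worst[1]} exceeds {cfg.rhat_threshold}")
    if divergences > cfg.divergence_cap:
        msgs.append(f"{divergences} divergent transitions exceed cap {cfg.divergence_cap}")
    for m in msgs:
        warnings.warn(m, RuntimeWarning, stacklevel=2)

    return PosteriorResult(
        spec=spec,
        draws=constrained,
        param_names=names,
        loglik=loglik,
        unconstrained=unconstrained,
        rhat=rhat,
        ess=ess,
        divergences=divergences,
        mean_accept=float(np.mean(accepts)),
        seed=seed,
        sampler_config=cfg,
        ok=not msgs,
        warnings_=msgs,
    )


def substantiality(
    result: PosteriorResult,
    parameter_family: str | list[str],
    level: float = 0.90,
) -> list[SlopeSummary]:
    """Exponentiated-slope summaries with the credible-interval rule.

    ``parameter_family`` is a name prefix (e.g. ``"mu:beta1_E"`` or
    ``"disp:species_slope"``) or an explicit list of parameter names.  For
    dispersion-side slopes of a Beta model the exponentiated draws are
    inverted so that values below 1 always mean increasing selection
    intensity (narrowing distribution).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if isinstance(parameter_family, str):
        names = result.names_matching(parameter_family)
        if not names:
            raise KeyError(f"no parameters match prefix {parameter_family!r}")
    else:
        names = list(parameter_family)
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    out = []
    fam = result.spec.family
    for nm in names:
        raw = result.flat(nm)
        raw_lo, raw_hi = np.quantile(raw, [lo_q, hi_q])
        ex = np.exp(raw)
        if nm.startswith("disp:") and fam.invert_disp_report:
            ex = 1.0 / ex
        lo, hi = np.quantile(ex, [lo_q, hi_q])
        med = float(np.median(ex))
        substantial = bool(lo > 1.0 or hi < 1.0)
        sign = 0
        if substantial:
            sign = 1 if lo > 1.0 else -1
        out.append(
            SlopeSummary(
                parameter=nm,
                exp_median=med,
                ci_low=float(lo),
                ci_high=float(hi),
                substantial=substantial,
                sign=sign,
                raw_ci_low=float(raw_lo),
                raw_ci_high=float(raw_hi),
                level=level,
            )
        )
    return out


_PPC_STATS = {
    "mean": lambda v: float(np.mean(v)),
    "cv": lambda v: float(np.std(v) / np.mean(v)) if np.mean(v) != 0 else np.nan,
    "q05": lambda v: float(np.quantile(v, 0.05)),
    "q95": lambda v: float(np.quantile(v, 0.95)),
}


def posterior_predictive_check(
    result: PosteriorResult,
    statistic: str = "mean",
    n_rep: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-community rank of the observed statistic within replicate datasets.

    Simulates ``n_rep`` full datasets from evenly spaced posterior draws and
    returns, per community, the fraction of replicates whose statistic falls
    below the observed one (mid-ranked at ties).  For a well-calibrated
    model ranks are roughly uniform; ranks < 0.01 or > 0.99 flag misfit.
    """
    if statistic not in _PPC_STATS:
        raise ValueError(f"statistic must be one of {sorted(_PPC_STATS)}")
    stat = _PPC_STATS[statistic]
    spec = result.spec
    communities = spec.meta["community"].to_numpy()
    unique_com = sorted(pd.unique(communities))
    if len(unique_com) == 0:
        return pd.DataFrame(columns=["community", "statistic", "observed", "rank"])
    layout = ParamLayout(spec)
    c, s, _ = result.unconstrained.shape
    total = c * s
    take = np.linspace(0, total - 1, min(n_rep, total)).astype(int)
    rng = np.random.default_rng(seed)
    flat_u = result.unconstrained.reshape(total, -1)

    obs = {com: stat(spec.y[communities == com]) for com in unique_com}
    below = {com: 0.0 for com in unique_com}
    n_used = 0
    for t in take:
        eta_mu, eta_di = layout.linear_predictors(flat_u[t])
        mu = spec.family.inv_link_mu(eta_mu)
        disp = spec.family.inv_link_disp(eta_di)
        y_rep = spec.family.sample(mu, disp, rng=rng, convention=spec.convention)
        for com in unique_com:
            v = stat(y_rep[communities == com])
            if v < obs[com]:
                below[com] += 1.0
            elif v == obs[com]:
                below[com] += 0.5
        n_used += 1
    rows = [
        dict(community=com, statistic=statistic, observed=obs[com],
             rank=below[com] / n_used)
        for com in unique_com
    ]
    return pd.DataFrame(rows)


def fit_species_mean_model(
    records: pd.DataFrame,
    trait: str,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
):
    """Fit the auxiliary species-mean model and return fitted values.

    The model has an intercept per campaign and a hierarchical species
    intercept (normal, estimated SD) on the mean's link scale.  Returns
    ``(fitted_values, result)`` where ``fitted_values`` maps
    ``(species, campaign)`` to the posterior-mean fitted trait value, for
    building the no-ITV dataset.
    """
    spec = build("M_means", trait, records)
    result = fit(spec, sampler_config=sampler_config, seed=seed)
    layout = ParamLayout(spec)
    c, s, _ = result.unconstrained.shape
    flat_u = result.unconstrained.reshape(c * s, -1)
    mu_sum = np.zeros(spec.n_obs)
    for t in range(flat_u.shape[0]):
        eta_mu, _ = layout.linear_predictors(flat_u[t])
        mu_sum += spec.family.inv_link_mu(eta_mu)
    mu_hat = mu_sum / flat_u.shape[0]
    fitted: dict[tuple[str, str], float] = {}
    for (sp, camp), idx in records.groupby(["species", "campaign"]).indices.items():
        fitted[(sp, camp)] = float(mu_hat[np.asarray(idx)].mean())
    return fitted, result
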