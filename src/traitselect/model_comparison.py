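"""Leave-one-out predictive density (PSIS) and Bayesian stacking weights.

``psis_loo`` approximates exact leave-one-out cross-validation from one
posterior sample: for each observation the importance ratios
``r_s = 1 / p(y_i | theta_s)`` are tail-smoothed by replacing the largest
20% with expected order statistics of a generalized Pareto distribution
fitted to them (the Pareto shape k̂ diagnosing reliability, with k̂ > 0.7
flagged), then truncated at ``S^{3/4}`` times their mean.  ``stacking_weights``
maximizes the pooled leave-one-out log predictive density of the weighted
model mixture over the simplex — the quantity behind the per-trait model
weight tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = ["LooResult", "StackingResult", "psis_loo", "stacking_weights", "compare_table"]

K_FLAG = 0.7

#: slope-term count used to break best-model ties toward simplicity
MODEL_COMPLEXITY = {
    "M_com0": 0, "M_com1": 1, "M_com2": 1, "M_com3": 2, "M_com3p": 2,
    "M_sp0": 2, "M_sp1": 2, "M_sp2": 2, "M_sp3": 2, "M_dens": 2,
}
_SLOPE_RANK = {"M_com0": 0, "M_com1": 1, "M_com2": 1, "M_com3": 2, "M_com3p": 3,
               "M_sp0": 0, "M_sp1": 1, "M_sp2": 1, "M_sp3": 2}


@dataclass
class LooResult:
    elpd_i: np.ndarray
    pareto_k: np.ndarray
    n_draws: int

    @property
    def elpd(self) -> float:
        return float(self.elpd_i.sum())

    @property
    def se(self) -> float:
        n = self.elpd_i.size
        return float(np.sqrt(n * np.var(self.elpd_i, ddof=1))) if n > 1 else 0.0

    @property
    def flagged(self) -> np.ndarray:
        return self.pareto_k > K_FLAG

    @property
    def n_obs(self) -> int:
        return self.elpd_i.size


@dataclass
class StackingResult:
    models: list[str]
    weights: np.ndarray
    loos: dict[str, LooResult]
    converged: bool
    n_iter: int
    objective: float


def _gpd_fit(x: np.ndarray):
    """Generalized Pareto fit to exceedances via the Zhang–Stephens
    empirical-Bayes profile method with the standard weak prior on k."""
    x = np.sort(x)
    n = x.size
    m = 30 + int(np.sqrt(n))
    prior_bs = 3.0
    bs = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    bs /= prior_bs * x[int(n / 4 + 0.5) - 1]
    bs += 1.0 / x[-1]
    ks = np.mean(np.log1p(-bs[:, None] * x[None, :]), axis=1)
    logl = n * (np.log(-bs / ks) - ks - 1.0)
    w = 1.0 / np.exp(logl - logl[:, None]).sum(axis=1)
    b = float(np.sum(bs * w))
    k = float(np.mean(np.log1p(-b * x)))
    sigma = -k / b
    k = k * n / (n + 10.0) + 0.25 * 10.0 / (n + 10.0)  # shrink toward 0.5
    return k, sigma


def _gpd_quantiles(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if np.abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_loo(loglik: np.ndarray, smooth: bool = True) -> LooResult:
    """PSIS leave-one-out from a (draws x observations) log-likelihood matrix.

    With ``smooth=False`` the tail fit is skipped and the estimate reduces to
    plain importance sampling (k̂ reported as NaN).
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be (draws, observations)")
    S, n = loglik.shape
    if S < 100:
        raise ValueError(f"need >= 100 draws for PSIS-LOO, got {S}")
    if not np.all(np.isfinite(loglik)):
        bad = np.argwhere(~np.isfinite(loglik))
        raise ValueError(
            f"non-finite log-likelihoods at (draw, observation) indices {bad[:5].tolist()}"
        )
    elpd_i = np.empty(n)
    khat = np.full(n, np.nan)
    tail_len = int(np.ceil(min(0.2 * S, 3.0 * np.sqrt(S))))
    for i in range(n):
        logr = -loglik[:, i]
        logr = logr - logr.max()
        logw = logr.copy()
        if smooth and tail_len >= 5:
            order = np.argsort(logr)
            tail_ids = order[-tail_len:]
            cutoff = logr[order[-tail_len - 1]]
            exceed = np.exp(logr[tail_ids]) - np.exp(cutoff)
            if np.ptp(exceed) > 0:
                k, sigma = _gpd_fit(exceed)
                khat[i] = k
                probs = (np.arange(1, tail_len + 1) - 0.5) / tail_len
                smoothed = np.log(_gpd_quantiles(probs, k, sigma) + np.exp(cutoff))
                # assign expected order statistics in ascending order
                logw[tail_ids[np.argsort(logr[tail_ids])]] = smoothed
            else:
                khat[i] = -np.inf
        # truncate at S^{3/4} * mean weight
        log_cap = logsumexp(logw) - np.log(S) + 0.75 * np.log(S)
        logw = np.minimum(logw, log_cap)
        elpd_i[i] = logsumexp(logw + loglik[:, i]) - logsumexp(logw)
    return LooResult(elpd_i=elpd_i, pareto_k=khat, n_draws=S)


def stacking_weights(loos: dict[str, LooResult] | list) -> StackingResult:
    """Maximize the pooled leave-one-out log predictive density over the simplex.

    The objective ``sum_i log sum_k w_k exp(elpd_ik)`` is concave in ``w``;
    it is solved with SLSQP from the uniform start with analytic gradient,
    so symmetric inputs return exactly uniform weights and the optimum is
    deterministic.
    """
    if isinstance(loos, dict):
        names = list(loos)
        loo_list = [loos[nm] for nm in names]
    else:
        names = [f"model_{k}" for k in range(len(loos))]
        loo_list = list(loos)
    if len(loo_list) == 0:
        raise ValueError("no models to stack")
    n_obs = {loo.n_obs for loo in loo_list}
    if len(n_obs) != 1:
        raise ValueError(f"models scored on different observation counts: {sorted(n_obs)}")
    K = len(loo_list)
    elpd = np.stack([loo.elpd_i for loo in loo_list], axis=1)  # (n, K)
    if K == 1:
        return StackingResult(names, np.array([1.0]), dict(zip(names, loo_list)),
                              True, 0, float(elpd.sum()))
    shift = elpd.max(axis=1, keepdims=True)
    p = np.exp(elpd - shift)  # (n, K), row max = 1

    def neg_obj(w):
        mix = p @ w
        return -float(np.sum(np.log(mix)))

    def neg_grad(w):
        mix = p @ w
        return -(p / mix[:, None]).sum(axis=0)

    w0 = np.full(K, 1.0 / K)
    res = minimize(
        neg_obj,
        w0,
        jac=neg_grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(K)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    objective = -neg_obj(w) + float(shift.sum())
    return StackingResult(
        models=names,
        weights=w,
        loos=dict(zip(names, loo_list)),
        converged=bool(res.success),
        n_iter=int(res.nit),
        objective=objective,
    )


def compare_table(trait: str, results: dict, model_set: list[str]) -> pd.DataFrame:
    """Stacking-weight table for one trait over a candidate model set.

    ``results`` maps model name to either a fitted
    :class:`~traitselect.inference.PosteriorResult` (its log-likelihood
    matrix is scored here) or a precomputed :class:`LooResult`.  The best
    model per trait is flagged, ties broken toward the model with fewer
    richness-slope terms.
    """
    loos: dict[str, LooResult] = {}
    for name in model_set:
        if name not in results:
            raise ValueError(f"missing fitted result for model {name!r}")
        obj = results[name]
        loos[name] = obj if isinstance(obj, LooResult) else psis_loo(obj.loglik)
    stack = stacking_weights(loos)
    order = sorted(
        range(len(stack.models)),
        key=lambda k: (-stack.weights[k], MODEL_COMPLEXITY.get(stack.models[k], 99),
                       _SLOPE_RANK.get(stack.models[k], 99)),
    )
    best = stack.models[order[0]]
    rows = []
    for name, w in zip(stack.models, stack.weights):
        loo = loos[name]
        rows.append(
            dict(
                trait=trait,
                model=name,
                weight=float(w),
                elpd=loo.elpd,
                elpd_se=loo.se,
                n_flagged_k=int(loo.flagged.sum()),
                best=(name == best),
            )
        )
    return pd.DataFrame(rows)
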