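"""A No-U-Turn sampler for differentiable log-posteriors.

Implements the dynamic-trajectory NUTS of Hoffman & Gelman (slice variant,
their Algorithm 6) with dual-averaging step-size adaptation and a diagonal
mass matrix estimated during warmup.  The interface is a plain function of
``logp_and_grad(theta) -> (float, ndarray)`` so any model with analytic
gradients can be sampled; the package's hierarchical distributional models
provide theirs in :mod:`traitselect._posterior`.

Warmup schedule: an initial step-size-only phase, one long window in which
posterior variances are accumulated for the metric, and a final step-size
phase after the metric update (a simplified version of the windowed scheme
used by mainstream samplers).  Divergences are flagged when the simulated
Hamiltonian error exceeds 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsConfig", "NutsResult", "sample_nuts"]

_MAX_DELTA = 1000.0  # Hamiltonian error marking a divergence


@dataclass(frozen=True)
class NutsConfig:
    warmup: int = 1000
    samples: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    init_jitter: float = 0.5


@dataclass
class NutsResult:
    draws: np.ndarray          # (samples, dim), unconstrained
    logp: np.ndarray           # (samples,)
    divergences: int
    mean_accept: float
    step_size: float
    inv_metric: np.ndarray
    treedepths: np.ndarray


def _find_initial_step(logp_and_grad, theta, inv_metric, rng):
    dim = theta.size
    eps = 1.0
    lp, grad = logp_and_grad(theta)
    p = rng.standard_normal(dim) / np.sqrt(inv_metric)
    h0 = lp - 0.5 * np.dot(p * inv_metric, p)

    def one_leap(eps):
        p1 = p + 0.5 * eps * grad
        t1 = theta + eps * inv_metric * p1
        lp1, g1 = logp_and_grad(t1)
        p1 = p1 + 0.5 * eps * g1
        return lp1 - 0.5 * np.dot(p1 * inv_metric, p1)

    h1 = one_leap(eps)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        h1 = one_leap(eps)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    """State carried through the recursive doubling."""

    __slots__ = ("theta_m", "p_m", "grad_m", "theta_p", "p_p", "grad_p",
                 "theta_prop", "n", "stop", "alpha", "n_alpha", "diverged")


def _leapfrog(logp_and_grad, theta, p, grad, eps, inv_metric):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_metric * p
    lp, grad = logp_and_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, grad, lp


def sample_nuts(logp_and_grad, theta0, config: NutsConfig, rng) -> NutsResult:
    """Run one chain; deterministic for a given ``rng`` state."""
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_metric = np.ones(dim)
    lp, grad = logp_and_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log-posterior at the initial point")

    eps = _find_initial_step(logp_and_grad, theta, inv_metric, rng)
    # dual averaging state; da_it restarts whenever the metric changes
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    da_it = 0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    delta = config.target_accept

    warmup, n_samples = config.warmup, config.samples
    # metric window: [w1, w2) of warmup
    w1 = max(int(0.15 * warmup), 1)
    w2 = max(int(0.9 * warmup), w1 + 1)
    acc = np.zeros(dim)
    acc2 = np.zeros(dim)
    n_acc = 0

    draws = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    depths = np.empty(n_samples, dtype=int)
    divergences = 0
    accept_sum, accept_n = 0.0, 0

    total = warmup + n_samples
    for it in range(total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_metric)
        h0 = lp - 0.5 * np.dot(p0 * inv_metric, p0)
        log_u = h0 + np.log(rng.uniform())

        theta_m = theta_p = theta
        p_m = p_p = p0
        grad_m = grad_p = grad
        theta_new, lp_new, grad_new = theta, lp, grad
        n_valid, stop = 1, False
        depth = 0
        it_diverged = False
        alpha_stat = 1.0

        while not stop and depth < config.max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                tree = _build_tree(logp_and_grad, theta_p, p_p, grad_p, log_u,
                                   direction, depth, eps, inv_metric, h0, rng)
                theta_p, p_p, grad_p = tree.theta_p, tree.p_p, tree.grad_p
            else:
                tree = _build_tree(logp_and_grad, theta_m, p_m, grad_m, log_u,
                                   direction, depth, eps, inv_metric, h0, rng)
                theta_m, p_m, grad_m = tree.theta_m, tree.p_m, tree.grad_m
            if tree.diverged:
                it_diverged = True
            if not tree.stop and tree.n > 0:
                if rng.uniform() < tree.n / max(n_valid, 1):
                    theta_new = tree.theta_prop
                    lp_new, grad_new = logp_and_grad(theta_new)
            n_valid += tree.n
            alpha_stat = tree.alpha / max(tree.n_alpha, 1)
            span = theta_p - theta_m
            stop = tree.stop or (np.dot(span, inv_metric * p_m) < 0) or (
                np.dot(span, inv_metric * p_p) < 0
            )
            depth += 1

        theta, lp, grad = theta_new, lp_new, grad_new

        if it < warmup:
            # dual averaging on a counter local to the current metric phase
            da_it += 1
            frac = 1.0 / (da_it + t0)
            h_bar = (1 - frac) * h_bar + frac * (delta - alpha_stat)
            log_eps = mu_da - np.sqrt(da_it) / gamma * h_bar
            w = da_it ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w1 <= it < w2:
                acc += theta
                acc2 += theta * theta
                n_acc += 1
            if it == w2 - 1 and n_acc > 10:
                var = acc2 / n_acc - (acc / n_acc) ** 2
                # regularize toward unit as mainstream samplers do
                inv_metric = (n_acc / (n_acc + 5.0)) * var + (5.0 / (n_acc + 5.0)) * 1e-3
                inv_metric = np.maximum(inv_metric, 1e-10)
                eps = _find_initial_step(logp_and_grad, theta, inv_metric, rng)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar = np.log(eps), 0.0
                da_it = 0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            j = it - warmup
            draws[j] = theta
            logps[j] = lp
            depths[j] = depth
            if it_diverged:
                divergences += 1
            accept_sum += alpha_stat
            accept_n += 1

    return NutsResult(
        draws=draws,
        logp=logps,
        divergences=divergences,
        mean_accept=accept_sum / max(accept_n, 1),
        step_size=eps,
        inv_metric=inv_metric,
        treedepths=depths,
    )


def _build_tree(logp_and_grad, theta, p, grad, log_u, direction, depth, eps,
                inv_metric, h0, rng) -> _Tree:
    tree = _Tree()
    if depth == 0:
        theta1, p1, grad1, lp1 = _leapfrog(
            logp_and_grad, theta, p, grad, direction * eps, inv_metric
        )
        h1 = lp1 - 0.5 * np.dot(p1 * inv_metric, p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        tree.theta_m = tree.theta_p = tree.theta_prop = theta1
        tree.p_m = tree.p_p = p1
        tree.grad_m = tree.grad_p = grad1
        tree.n = int(log_u <= h1)
        tree.diverged = (log_u - _MAX_DELTA) > h1
        tree.stop = tree.diverged
        tree.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
        tree.n_alpha = 1
        return tree

    left = _build_tree(logp_and_grad, theta, p, grad, log_u, direction,
                       depth - 1, eps, inv_metric, h0, rng)
    tree.theta_m, tree.p_m, tree.grad_m = left.theta_m, left.p_m, left.grad_m
    tree.theta_p, tree.p_p, tree.grad_p = left.theta_p, left.p_p, left.grad_p
    tree.theta_prop = left.theta_prop
    tree.n, tree.stop = left.n, left.stop
    tree.alpha, tree.n_alpha = left.alpha, left.n_alpha
    tree.diverged = left.diverged
    if not tree.stop:
        if direction == 1:
            right = _build_tree(logp_and_grad, tree.theta_p, tree.p_p, tree.grad_p,
                                log_u, direction, depth - 1, eps, inv_metric, h0, rng)
            tree.theta_p, tree.p_p, tree.grad_p = right.theta_p, right.p_p, right.grad_p
        else:
            right = _build_tree(logp_and_grad, tree.theta_m, tree.p_m, tree.grad_m,
                                log_u, direction, depth - 1, eps, inv_metric, h0, rng)
            tree.theta_m, tree.p_m, tree.grad_m = right.theta_m, right.p_m, right.grad_m
        if right.n > 0 and rng.uniform() < right.n / max(tree.n + right.n, 1):
            tree.theta_prop = right.theta_prop
        tree.n += right.n
        tree.alpha += right.alpha
        tree.n_alpha += right.n_alpha
        tree.diverged = tree.diverged or right.diverged
        span = tree.theta_p - tree.theta_m
        tree.stop = right.stop or (np.dot(span, inv_metric * tree.p_m) < 0) or (
            np.dot(span, inv_metric * tree.p_p) < 0
        )
    return tree
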