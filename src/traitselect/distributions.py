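"""Mean–dispersion Gamma and mean–precision Beta families.

Distributional regression places a linear predictor on *every* parameter of
the response distribution, so both families are parameterized by their mean
and a dispersion-like quantity rather than by shape/scale:

* ``gamma``: mean ``mu > 0`` and dispersion ``sigma > 0``.  Under the default
  convention ``sigma`` is the coefficient of variation, i.e. shape
  ``alpha = 1/sigma**2`` and scale ``theta = mu*sigma**2`` so that
  ``E[y] = mu`` and ``SD[y] = sigma*mu``.  An alternative convention
  (``sigma = 1/shape``) is available via ``convention="inverse_shape"``.
* ``beta``: mean ``mu in (0,1)`` and precision ``phi > 0``, i.e.
  ``a = mu*phi``, ``b = (1-mu)*phi`` and ``Var[y] = mu*(1-mu)/(1+phi)``.

Links are ``log`` for gamma mean and dispersion, ``logit`` for the beta mean
and ``log`` for the beta precision.  These make an exponentiated slope a
multiplicative effect on the mean or dispersion, which is how richness
slopes are interpreted downstream.  Because a *larger* beta precision means a
*smaller* dispersion, reporting code inverts exponentiated phi-slopes so that
values below 1 always read "dispersion shrinks" (see
:func:`traitselect.inference.substantiality`).

The module also exposes the score functions (derivatives of the log-density
with respect to the link-scale predictors) used by the gradient-based
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit, gammaln

__all__ = [
    "FamilySpec",
    "GAMMA",
    "BETA",
    "get_family",
    "gamma_logpdf",
    "beta_logpdf",
    "sample",
]


@dataclass(frozen=True)
class FamilySpec:
    """A response family together with its link functions.

    Attributes
    ----------
    name:
        ``"gamma"`` or ``"beta"``.
    link_mu, link_disp:
        Names of the link functions for the mean and the dispersion-like
        parameter.
    disp_name:
        ``"sigma"`` (gamma dispersion) or ``"phi"`` (beta precision).
    invert_disp_report:
        Whether exponentiated dispersion-side slopes must be inverted at
        reporting time so that values < 1 always mean a narrowing
        distribution (true only for the beta precision).
    """

    name: str
    link_mu: str
    link_disp: str
    disp_name: str
    invert_disp_report: bool

    # -- link functions -------------------------------------------------
    def inv_link_mu(self, eta: np.ndarray) -> np.ndarray:
        if self.link_mu == "log":
            return np.exp(eta)
        return expit(eta)

    def inv_link_disp(self, eta: np.ndarray) -> np.ndarray:
        return np.exp(eta)

    def link_mu_fn(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        if self.link_mu == "log":
            return np.log(mu)
        return np.log(mu) - np.log1p(-mu)

    # -- densities ------------------------------------------------------
    def logpdf(self, y, mu, disp, convention: str = "cv"):
        if self.name == "gamma":
            return gamma_logpdf(y, mu, disp, convention=convention)
        return beta_logpdf(y, mu, disp)

    def sample(self, mu, disp, n=None, rng=None, convention: str = "cv"):
        return sample(self.name, mu, disp, n=n, rng=rng, convention=convention)

    # -- score functions on the link scale ------------------------------
    def score_eta(self, y, eta_mu, eta_disp, convention: str = "cv"):
        """d logpdf / d(eta_mu), d logpdf / d(eta_disp), elementwise."""
        if self.name == "gamma":
            return _gamma_score_eta(y, eta_mu, eta_disp, convention)
        return _beta_score_eta(y, eta_mu, eta_disp)

    def loglik_and_scores(self, y, eta_mu, eta_disp, convention: str = "cv"):
        """Fused log-density and link-scale scores (shared special functions).

        Hot path of the sampler; ``log(y)`` / ``log1p(-y)`` may be passed
        precomputed via the ``logy``/``log1my`` keywords of the private
        implementations by callers that loop.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if self.name == "gamma":
                c = 2.0 if convention == "cv" else 1.0
                alpha = np.exp(-c * eta_disp)
                log_theta = eta_mu + c * eta_disp
                logy = np.log(y)
                y_over_theta = y * np.exp(-log_theta)
                ll = -gammaln(alpha) - alpha * log_theta + (alpha - 1.0) * logy - y_over_theta
                dl_dlogtheta = y_over_theta - alpha
                dl_dalpha = -digamma(alpha) - log_theta + logy
                s_mu = dl_dlogtheta
                s_disp = c * (dl_dlogtheta - alpha * dl_dalpha)
                return ll, s_mu, s_disp
            mu = expit(eta_mu)
            phi = np.exp(eta_disp)
            a = mu * phi
            b = (1.0 - mu) * phi
            logy = np.log(y)
            log1my = np.log1p(-y)
            dga, dgb = digamma(a), digamma(b)
            ll = (
                gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1.0) * logy + (b - 1.0) * log1my
            )
            s_mu = phi * mu * (1.0 - mu) * ((logy - log1my) - (dga - dgb))
            s_disp = phi * (
                digamma(phi) - mu * dga - (1.0 - mu) * dgb + mu * logy + (1.0 - mu) * log1my
            )
            return ll, s_mu, s_disp

    def logpdf_eta(self, y, eta_mu, eta_disp, convention: str = "cv"):
        """Log-density directly from link-scale predictors.

        Written to stay finite wherever possible for extreme predictors (the
        sampler probes these during step-size search); invalid combinations
        come back ``-inf`` / ``nan`` rather than raising.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if self.name == "gamma":
                c = 2.0 if convention == "cv" else 1.0
                alpha = np.exp(-c * eta_disp)
                log_theta = eta_mu + c * eta_disp
                return (
                    -gammaln(alpha)
                    - alpha * log_theta
                    + (alpha - 1.0) * np.log(y)
                    - y * np.exp(-log_theta)
                )
            mu = expit(eta_mu)
            phi = np.exp(eta_disp)
            a = mu * phi
            b = (1.0 - mu) * phi
            return (
                gammaln(phi)
                - gammaln(a)
                - gammaln(b)
                + (a - 1.0) * np.log(y)
                + (b - 1.0) * np.log1p(-y)
            )


GAMMA = FamilySpec("gamma", "log", "log", "sigma", invert_disp_report=False)
BETA = FamilySpec("beta", "logit", "log", "phi", invert_disp_report=True)

_FAMILIES = {"gamma": GAMMA, "beta": BETA}


def get_family(name: str) -> FamilySpec:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; expected 'gamma' or 'beta'")


def _gamma_shape_scale(mu, sigma, convention):
    if convention == "cv":
        alpha = 1.0 / np.square(sigma)
        theta = mu * np.square(sigma)
    elif convention == "inverse_shape":
        alpha = 1.0 / sigma
        theta = mu * sigma
    else:
        raise ValueError(f"unknown gamma convention {convention!r}")
    return alpha, theta


def gamma_logpdf(y, mu, sigma, convention: str = "cv"):
    """Log-density of the mean–dispersion Gamma.

    With the default ``convention="cv"``, shape ``alpha = 1/sigma**2`` and
    scale ``theta = mu*sigma**2``, so the mean is ``mu`` and ``sigma`` is the
    coefficient of variation.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(y <= 0) or np.any(~np.isfinite(y)):
        raise ValueError("gamma_logpdf: y must be finite and > 0")
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("gamma_logpdf: mu and sigma must be > 0")
    alpha, theta = _gamma_shape_scale(mu, sigma, convention)
    return -gammaln(alpha) - alpha * np.log(theta) + (alpha - 1.0) * np.log(y) - y / theta


def beta_logpdf(y, mu, phi):
    """Log-density of the mean–precision Beta: ``a = mu*phi``, ``b = (1-mu)*phi``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("beta_logpdf: y must lie strictly inside (0, 1)")
    if np.any(mu <= 0) or np.any(mu >= 1) or np.any(phi <= 0):
        raise ValueError("beta_logpdf: need 0 < mu < 1 and phi > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def sample(family: str, mu, disp, n=None, rng=None, convention: str = "cv"):
    """Draw from a family; ``rng`` is an ``np.random.Generator`` or a seed."""
    if n is not None and n < 1:
        raise ValueError("sample: n must be >= 1")
    rng = np.random.default_rng(rng)
    mu = np.asarray(mu, dtype=float)
    disp = np.asarray(disp, dtype=float)
    if family == "gamma":
        if np.any(mu <= 0) or np.any(disp <= 0):
            raise ValueError("gamma sample: mu and sigma must be > 0")
        alpha, theta = _gamma_shape_scale(mu, disp, convention)
        return rng.gamma(shape=alpha, scale=theta, size=n)
    if family == "beta":
        if np.any(mu <= 0) or np.any(mu >= 1) or np.any(disp <= 0):
            raise ValueError("beta sample: need 0 < mu < 1 and phi > 0")
        return rng.beta(mu * disp, (1.0 - mu) * disp, size=n)
    raise ValueError(f"unknown family {family!r}")


def _gamma_score_eta(y, eta_mu, eta_sigma, convention):
    """Scores of the gamma log-density w.r.t. eta_mu = log(mu), eta_sigma = log(sigma)."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        mu = np.exp(eta_mu)
        sigma = np.exp(eta_sigma)
        alpha, theta = _gamma_shape_scale(mu, sigma, convention)
        # d logpdf / d log(theta) holding alpha fixed:
        dl_dlogtheta = y / theta - alpha
        # d logpdf / d alpha holding theta fixed:
        dl_dalpha = -digamma(alpha) - np.log(theta) + np.log(y)
        # log(theta) = log(mu) + c*log(sigma); alpha = sigma**-c, c = 2 (cv) or 1.
        c = 2.0 if convention == "cv" else 1.0
        s_mu = dl_dlogtheta
        s_sigma = c * (dl_dlogtheta - alpha * dl_dalpha)
        return s_mu, s_sigma


def _beta_score_eta(y, eta_mu, eta_phi):
    """Scores of the beta log-density w.r.t. eta_mu = logit(mu), eta_phi = log(phi)."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        mu = expit(eta_mu)
        phi = np.exp(eta_phi)
        a = mu * phi
        b = (1.0 - mu) * phi
        logit_y = np.log(y) - np.log1p(-y)
        s_mu = phi * mu * (1.0 - mu) * (logit_y - (digamma(a) - digamma(b)))
        dl_dphi = (
            digamma(phi)
            - mu * digamma(a)
            - (1.0 - mu) * digamma(b)
            + mu * np.log(y)
            + (1.0 - mu) * np.log1p(-y)
        )
        s_phi = phi * dl_dphi
        return s_mu, s_phi
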