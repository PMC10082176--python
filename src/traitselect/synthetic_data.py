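"""Synthetic wetland study designs and individual-level trait data.

The generator reproduces the statistical structure of a replicated
species-richness gradient: 4 wetland ecosystems ordered by soil fertility,
8 communities per ecosystem (7 in the wet meadow, 31 in total) spanning
richness 2–16 over ~20–25 m² plots, 80 ramets sampled per community across
2 campaigns by 2 harvesters, with 7 functional traits per ramet and a
point–plant distance for density estimation.

Trait values are drawn from the same hierarchical distributional models the
inference module fits: each trait has a Gamma (positive traits) or Beta
(LDMC) response whose mean and dispersion both carry linear predictors with
campaign intercepts, ecosystem deviations, hierarchical community
deviations, ecosystem- or species-level richness slopes, and a correlated
multinormal species block.  Fitting the matching model to data from this
generator is therefore a direct parameter-recovery experiment.

Distances come from a homogeneous Poisson point pattern on a square plot
with toroidal wrap (side = sqrt(area)), so nearest-point distances follow
the Rayleigh law with mean 1/(2*sqrt(intensity)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .distributions import get_family

__all__ = [
    "TRAITS",
    "DesignConfig",
    "Community",
    "StudyDesign",
    "TraitParams",
    "make_design",
    "preset_parameters",
    "simulate_traits",
    "simulate_point_plant_distances",
    "nearest_point_distances",
    "species_mean_dataset",
]

#: trait name -> family; LDMC is a (0,1) mass fraction, everything else positive
TRAITS: dict[str, str] = {
    "angle": "gamma",
    "EL": "gamma",
    "LA": "gamma",
    "SLA": "gamma",
    "chlorophyll": "gamma",
    "LDMC": "beta",
    "flavonoid": "gamma",
}

RICHNESS_BOUNDS = (2, 16)


@dataclass
class DesignConfig:
    """Knobs of the synthetic study design (defaults = the full field design)."""

    ecosystems: tuple[str, ...] = ("bog", "fen", "meadow", "marsh")
    #: communities per ecosystem; the wet meadow has one fewer
    communities_per_ecosystem: tuple[int, ...] = (8, 8, 7, 8)
    richness_range: tuple[int, int] = RICHNESS_BOUNDS
    n_per_community: int = 80
    campaigns: tuple[str, ...] = ("T1", "T2")
    pool_size: int = 20
    n_core_species: int = 3
    #: per-ecosystem lower end of the richness gradient; the gradients are
    #: comparable but not identical across ecosystems, and a community at the
    #: low extreme can only contain core species, so alternating 2/3 minima
    #: yields ~11 focal species (3+2 cores per ecosystem pass the
    #: both-extremes rule) as in the emulated field design
    richness_min_per_ecosystem: tuple[int, ...] | None = (2, 3, 2, 3)
    #: symmetric Dirichlet concentration for within-community relative
    #: densities; < 1 produces the monodominance typical of poor communities
    dirichlet_concentration: float = 0.6
    area_range: tuple[float, float] = (20.0, 25.0)
    flowering_rate: float = 0.079
    strict: bool = True


@dataclass
class Community:
    ecosystem: str
    community_id: str
    richness: int
    area_m2: float
    species: list[str]
    rel_density: np.ndarray  # sums to 1, one entry per present species


@dataclass
class StudyDesign:
    ecosystems: list[str]           # ordered by soil-fertility rank
    communities: list[Community]
    campaigns: tuple[str, ...]
    n_per_community: int
    config: DesignConfig

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @property
    def n_records(self) -> int:
        return self.n_communities * self.n_per_community

    def species_pool(self, ecosystem: str) -> list[str]:
        seen: list[str] = []
        for com in self.communities:
            if com.ecosystem == ecosystem:
                for sp in com.species:
                    if sp not in seen:
                        seen.append(sp)
        return seen

    def community_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    ecosystem=c.ecosystem,
                    community=c.community_id,
                    richness=c.richness,
                    area_m2=c.area_m2,
                    n_species=len(c.species),
                )
                for c in self.communities
            ]
        )


def _spread_richness(lo: int, hi: int, k: int) -> list[int]:
    """k integer richness values covering [lo, hi], both endpoints included."""
    vals = np.rint(np.linspace(lo, hi, k)).astype(int)
    vals[0], vals[-1] = lo, hi
    return vals.tolist()


def make_design(config: DesignConfig | None = None, seed: int = 0) -> StudyDesign:
    """Instantiate a study design; deterministic for fixed (config, seed)."""
    cfg = config or DesignConfig()
    lo, hi = cfg.richness_range
    if cfg.strict and (lo < RICHNESS_BOUNDS[0] or hi > RICHNESS_BOUNDS[1] or lo > hi):
        raise ValueError(
            f"richness range {cfg.richness_range} outside {RICHNESS_BOUNDS} with strict=True"
        )
    if cfg.n_per_community < 1:
        raise ValueError("n_per_community must be >= 1")
    if len(cfg.communities_per_ecosystem) != len(cfg.ecosystems):
        raise ValueError("communities_per_ecosystem must match ecosystems")

    mins = cfg.richness_min_per_ecosystem
    if mins is not None and len(mins) != len(cfg.ecosystems):
        raise ValueError("richness_min_per_ecosystem must match ecosystems")

    rng = np.random.default_rng(seed)
    communities: list[Community] = []
    for i_eco, (eco, n_com) in enumerate(
        zip(cfg.ecosystems, cfg.communities_per_ecosystem)
    ):
        lo_e = lo if mins is None else max(lo, mins[i_eco])
        pool = [f"{eco}_sp{j:02d}" for j in range(1, cfg.pool_size + 1)]
        core = pool[: cfg.n_core_species]
        extras = pool[cfg.n_core_species:]
        # geometric inclusion weights make a few extras "frequent"
        w = 0.7 ** np.arange(len(extras))
        richness_vals = _spread_richness(lo_e, hi, n_com)
        for k, D in enumerate(richness_vals, start=1):
            n_core = min(D, len(core))
            members = list(core[:n_core])
            n_extra = D - n_core
            if n_extra > len(extras):
                raise ValueError(
                    f"species pool of {eco} too small for richness {D}"
                )
            if n_extra > 0:
                probs = w / w.sum()
                chosen = rng.choice(len(extras), size=n_extra, replace=False, p=probs)
                members += [extras[i] for i in sorted(chosen)]
            # largest shares go to the core species: the persistent taxa
            # dominate, giving the monodominance seen in species-poor plots
            # while keeping the symmetric-Dirichlet shape of the abundances
            rel = np.sort(rng.dirichlet(np.full(D, cfg.dirichlet_concentration)))[::-1]
            area = float(rng.uniform(*cfg.area_range))
            communities.append(
                Community(
                    ecosystem=eco,
                    community_id=f"{eco}_c{k}",
                    richness=int(D),
                    area_m2=area,
                    species=members,
                    rel_density=rel,
                )
            )
    return StudyDesign(
        ecosystems=list(cfg.ecosystems),
        communities=communities,
        campaigns=cfg.campaigns,
        n_per_community=cfg.n_per_community,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# True generative parameters
# ---------------------------------------------------------------------------


@dataclass
class TraitParams:
    """Link-scale coefficients of one trait's generative distributional model.

    ``beta_*`` act on the mean predictor, ``gamma_*`` on the
    dispersion/precision predictor.  ``sd_species`` and ``corr_species`` give
    the 4-dimensional multinormal for per-species (deviation_mu,
    deviation_disp, slope_mu, slope_disp) effects.
    """

    family: str
    beta0: float
    beta_T2: float = 0.0
    beta_E: dict[str, float] = field(default_factory=dict)
    sd_beta_C: float = 0.0
    beta1_E: dict[str, float] = field(default_factory=dict)
    gamma0: float = 0.0
    gamma_T2: float = 0.0
    gamma_E: dict[str, float] = field(default_factory=dict)
    sd_gamma_C: float = 0.0
    gamma1_E: dict[str, float] = field(default_factory=dict)
    sd_species: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    corr_species: np.ndarray | None = None  # 4x4, defaults to identity

    def species_cov(self) -> np.ndarray:
        sd = np.asarray(self.sd_species, dtype=float)
        corr = np.eye(4) if self.corr_species is None else np.asarray(self.corr_species)
        if not np.allclose(corr, corr.T):
            raise ValueError("corr_species must be symmetric")
        cov = np.outer(sd, sd) * corr
        # guard: positive semi-definite
        eigvals = np.linalg.eigvalsh(corr)
        if np.any(eigvals < -1e-10):
            raise ValueError("corr_species must be positive semi-definite")
        return cov

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.corr_species is not None:
            d["corr_species"] = np.asarray(self.corr_species).tolist()
        d["sd_species"] = list(self.sd_species)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TraitParams":
        d = dict(d)
        if d.get("corr_species") is not None:
            d["corr_species"] = np.asarray(d["corr_species"], dtype=float)
        d["sd_species"] = tuple(d["sd_species"])
        return cls(**d)


def _eco_dev(values: list[float], ecosystems: tuple[str, ...]) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    v = v - v.mean()  # deviations from the overall mean, sum-to-zero
    return dict(zip(ecosystems, v.tolist()))


def preset_parameters(name: str = "bog-like", ecosystems=("bog", "fen", "meadow", "marsh")) -> dict[str, TraitParams]:
    """Reproducible true-parameter sets for all seven traits.

    These are package fixtures with plausible wetland magnitudes, not field
    estimates.  "bog-like" has mild richness effects on means and dispersions;
    "marsh-like" has taller plants, larger leaves and stronger slopes.
    """
    if name == "bog-like":
        mu_slope, disp_slope = np.log(1.02), np.log(1.03)
        means = dict(angle=45.0, EL=25.0, LA=30.0, SLA=14.0, chlorophyll=22.0, flavonoid=1.2)
        ldmc_mean = 0.28
    elif name == "marsh-like":
        mu_slope, disp_slope = np.log(1.04), np.log(1.05)
        means = dict(angle=55.0, EL=60.0, LA=55.0, SLA=18.0, chlorophyll=28.0, flavonoid=0.9)
        ldmc_mean = 0.20
    else:
        raise ValueError(f"unknown preset {name!r}")

    E = len(ecosystems)
    eco_pattern = list(np.linspace(-0.15, 0.15, E))
    params: dict[str, TraitParams] = {}
    for trait, mean in means.items():
        params[trait] = TraitParams(
            family="gamma",
            beta0=float(np.log(mean)),
            beta_T2=0.05,
            beta_E=_eco_dev(eco_pattern, ecosystems),
            sd_beta_C=0.08,
            beta1_E={e: float(mu_slope) for e in ecosystems},
            gamma0=float(np.log(0.30)),
            gamma_T2=-0.02,
            gamma_E=_eco_dev(eco_pattern[::-1], ecosystems),
            sd_gamma_C=0.08,
            gamma1_E={e: float(disp_slope) for e in ecosystems},
            sd_species=(0.15, 0.10, 0.01, 0.01),
        )
    params["LDMC"] = TraitParams(
        family="beta",
        beta0=float(np.log(ldmc_mean / (1 - ldmc_mean))),
        beta_T2=0.05,
        beta_E=_eco_dev(eco_pattern, ecosystems),
        sd_beta_C=0.08,
        beta1_E={e: float(mu_slope) for e in ecosystems},
        gamma0=float(np.log(30.0)),
        gamma_T2=-0.02,
        gamma_E=_eco_dev(eco_pattern[::-1], ecosystems),
        sd_gamma_C=0.08,
        # precision slope: negative log-slope = dispersion grows with richness
        gamma1_E={e: float(-disp_slope) for e in ecosystems},
        sd_species=(0.15, 0.10, 0.01, 0.01),
    )
    return params


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_species_effects(design: StudyDesign, tp: TraitParams, rng) -> dict[str, np.ndarray]:
    cov = tp.species_cov()
    out = {}
    for eco in design.ecosystems:
        for sp in design.species_pool(eco):
            if sp not in out:
                if np.allclose(cov, 0):
                    out[sp] = np.zeros(4)
                else:
                    out[sp] = rng.multivariate_normal(np.zeros(4), cov, method="cholesky")
    return out


def simulate_traits(
    design: StudyDesign,
    true_params: dict[str, TraitParams],
    seed: int = 0,
    traits: list[str] | None = None,
    return_effects: bool = False,
):
    """Draw an individual-level dataset from the generative models.

    Species are assigned within each community proportionally to the
    community's true relative densities; campaigns and harvesters split the
    80 samples evenly (40/40 and 20/20 within campaign).
    """
    traits = list(true_params) if traits is None else traits
    for t in traits:
        if t not in true_params:
            raise ValueError(f"no true parameters for trait {t!r}")
    rng = np.random.default_rng(seed)

    rows = []
    for com in design.communities:
        n = design.n_per_community
        sp_idx = rng.choice(len(com.species), size=n, p=com.rel_density)
        half = n // 2
        for i in range(n):
            campaign = design.campaigns[0] if i < half else design.campaigns[-1]
            harvester = 1 + (i % 2)
            rows.append(
                dict(
                    ecosystem=com.ecosystem,
                    community=com.community_id,
                    campaign=campaign,
                    harvester=harvester,
                    species=com.species[sp_idx[i]],
                    richness=com.richness,
                    area_m2=com.area_m2,
                    flowering=bool(rng.random() < design.config.flowering_rate),
                )
            )
    records = pd.DataFrame(rows)
    D = records["richness"].to_numpy(dtype=float)
    is_T2 = (records["campaign"] == design.campaigns[-1]).to_numpy()

    effects: dict[str, dict] = {}
    for trait in traits:
        tp = true_params[trait]
        fam = get_family(tp.family)
        com_dev_mu = {c.community_id: rng.normal(0.0, tp.sd_beta_C) if tp.sd_beta_C > 0 else 0.0
                      for c in design.communities}
        com_dev_di = {c.community_id: rng.normal(0.0, tp.sd_gamma_C) if tp.sd_gamma_C > 0 else 0.0
                      for c in design.communities}
        sp_eff = _draw_species_effects(design, tp, rng)

        eta_mu = np.full(len(records), tp.beta0)
        eta_di = np.full(len(records), tp.gamma0)
        eta_mu[is_T2] += tp.beta_T2
        eta_di[is_T2] += tp.gamma_T2
        eco = records["ecosystem"].to_numpy()
        com = records["community"].to_numpy()
        sp = records["species"].to_numpy()
        eta_mu += np.array([tp.beta_E.get(e, 0.0) for e in eco])
        eta_di += np.array([tp.gamma_E.get(e, 0.0) for e in eco])
        eta_mu += np.array([com_dev_mu[c] for c in com])
        eta_di += np.array([com_dev_di[c] for c in com])
        eta_mu += np.array([tp.beta1_E.get(e, 0.0) for e in eco]) * D
        eta_di += np.array([tp.gamma1_E.get(e, 0.0) for e in eco]) * D
        se = np.array([sp_eff[s] for s in sp])
        eta_mu += se[:, 0] + se[:, 2] * D
        eta_di += se[:, 1] + se[:, 3] * D

        if not (np.all(np.isfinite(eta_mu)) and np.all(np.isfinite(eta_di))):
            bad = np.flatnonzero(~(np.isfinite(eta_mu) & np.isfinite(eta_di)))[0]
            raise ValueError(
                f"non-finite linear predictor for trait {trait!r} at row {bad}; "
                "check the coefficients of its TraitParams"
            )
        mu = fam.inv_link_mu(eta_mu)
        disp = fam.inv_link_disp(eta_di)
        records[trait] = fam.sample(mu, disp, rng=rng)
        effects[trait] = dict(community_mu=com_dev_mu, community_disp=com_dev_di,
                              species=sp_eff)

    if return_effects:
        return records, effects
    return records


def nearest_point_distances(intensity: float, n: int, area_m2: float = 22.0,
                            rng=None) -> np.ndarray:
    """Nearest-individual distances (cm) from random points over a homogeneous
    Poisson pattern of the given intensity (ind m^-2) on a toroidal square plot."""
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    rng = np.random.default_rng(rng)
    side = np.sqrt(area_m2)
    n_pts = rng.poisson(intensity * area_m2)
    n_pts = max(n_pts, 1)
    plants = rng.uniform(0.0, side, size=(n_pts, 2))
    tree = cKDTree(plants, boxsize=side)  # toroidal wrap
    samples = rng.uniform(0.0, side, size=(n, 2))
    d_m, _ = tree.query(samples)
    return d_m * 100.0


def simulate_point_plant_distances(
    records: pd.DataFrame,
    design: StudyDesign,
    intensity: float | dict[str, float] = 200.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach point–plant distances (cm) to every record.

    ``intensity`` is the total plant density per community (ind m^-2),
    either a scalar or a per-community mapping.  One Poisson pattern is
    simulated per community and each record receives the distance from an
    independent random point to its nearest plant.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    out["distance_cm"] = np.nan
    for com in design.communities:
        lam = intensity[com.community_id] if isinstance(intensity, dict) else intensity
        if lam <= 0:
            raise ValueError(f"intensity for {com.community_id} must be > 0")
        mask = out["community"] == com.community_id
        n = int(mask.sum())
        if n:
            out.loc[mask, "distance_cm"] = nearest_point_distances(
                lam, n, area_m2=com.area_m2, rng=rng
            )
    return out


def species_mean_dataset(records: pd.DataFrame, trait: str,
                         fitted_values: dict) -> pd.DataFrame:
    """Replace a trait's individual values by fitted species means.

    ``fitted_values`` maps ``(species, campaign)`` to the posterior-mean
    fitted trait value from a species-mean model (campaign intercepts plus a
    hierarchical species intercept).  Used to build the no-ITV counterfactual
    dataset: the returned table has zero within-(species, campaign) variance
    in ``trait`` and is otherwise identical.
    """
    out = records.copy()
    keys = list(zip(records["species"], records["campaign"]))
    missing = sorted({k[0] for k in keys if k not in fitted_values})
    if missing:
        raise ValueError(f"species missing from the fitted species-mean model: {missing}")
    out[trait] = [float(fitted_values[k]) for k in keys]
    return out
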