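"""Candidate distributional models as declarative specifications.

Every model regresses both the mean and the dispersion/precision of a trait
on study-design covariates.  The community-level set asks whether species
richness D_c shifts the mean (selection directionality), the dispersion
(selection intensity), neither, or both:

* ``M_com0`` — campaign intercepts, ecosystem deviations and hierarchical
  community deviations on both sides; no richness terms.
* ``M_com1`` — adds a per-ecosystem richness slope on the mean only.
* ``M_com2`` — the slope on the dispersion only.
* ``M_com3`` — slopes on both sides.
* ``M_com3p`` — ``M_com3`` refitted to the no-ITV dataset in which each
  individual's value is replaced by its fitted species mean.

The species-level set replaces "one slope per ecosystem" by "one slope per
focal species" on either side; species deviations and any per-species
slopes are jointly multinormal with an estimated covariance (LKJ prior):

* ``M_sp0`` — ecosystem slopes on both sides (species block: deviations only).
* ``M_sp1`` — species slopes on the mean, ecosystem slopes on the dispersion.
* ``M_sp2`` — the opposite syndrome.
* ``M_sp3`` — species slopes on both sides.
* ``M_dens`` — the ``M_sp3`` structure with per-(species, community) density
  as the Gamma response and no campaign term (density pools campaigns).

``M_means`` is the auxiliary species-mean model (campaign intercepts plus a
hierarchical species intercept) used to construct the no-ITV dataset.

Contrasts: campaign 1 is the reference, ecosystem deviations are
sum-to-zero, the richness covariate enters raw (per-species units) so an
exponentiated slope is the multiplicative change per added species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import FamilySpec, get_family
from .synthetic_data import TRAITS

__all__ = [
    "PriorConfig",
    "HierGroup",
    "SpeciesBlock",
    "TraitModelSpec",
    "COMMUNITY_MODELS",
    "SPECIES_MODELS",
    "build",
    "focal_species_filter",
]

COMMUNITY_MODELS = ("M_com0", "M_com1", "M_com2", "M_com3", "M_com3p")
SPECIES_MODELS = ("M_sp0", "M_sp1", "M_sp2", "M_sp3")
_ALL_MODELS = COMMUNITY_MODELS + SPECIES_MODELS + ("M_dens", "M_means")

BETA_EPS = 1e-4  # clamp for (0,1) responses before Beta fitting


@dataclass(frozen=True)
class PriorConfig:
    """Priors on link-scale parameters (configurable, weakly informative)."""

    fixed_sd: float = 2.5        # normal(0, fixed_sd) on fixed coefficients
    hier_sd_scale: float = 1.0   # half-normal(0, scale) on hierarchical SDs
    lkj_eta: float = 2.0         # LKJ shape on the species-block correlation


@dataclass
class HierGroup:
    """One hierarchical deviation term (e.g. community intercepts) on one side."""

    name: str
    side: str                  # "mu" or "disp"
    levels: list[str]
    index: np.ndarray          # (n,) int codes into levels

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class SpeciesBlock:
    """Correlated multinormal species effects.

    ``components`` lists (side, kind) pairs, kind "dev" (multiplier 1) or
    "slope" (multiplier = centered richness); the per-species effect vectors
    across components share one correlation matrix with an LKJ prior.

    The slope multiplier is richness centered at its sample mean, so a
    species "deviation" is its offset in an average-richness community.
    This leaves every slope (the reported quantity) untouched while removing
    the near-perfect deviation/slope collinearity a raw covariate induces.
    """

    species: list[str]
    index: np.ndarray          # (n,) int codes into species
    components: list[tuple[str, str]]
    richness: np.ndarray       # (n,) raw richness covariate

    @property
    def dim(self) -> int:
        return len(self.components)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def multiplier(self, j: int) -> np.ndarray:
        side, kind = self.components[j]
        if kind == "slope":
            return self.richness - self.richness.mean()
        return np.ones_like(self.richness)


@dataclass
class TraitModelSpec:
    """A fully materialized model: response, design matrices, hierarchy, priors."""

    name: str
    trait: str
    family: FamilySpec
    level: str                     # "community" | "species" | "density" | "auxiliary"
    y: np.ndarray
    X_mu: np.ndarray
    X_disp: np.ndarray
    names_mu: list[str]
    names_disp: list[str]
    groups: list[HierGroup]
    species_block: SpeciesBlock | None
    priors: PriorConfig
    meta: pd.DataFrame
    convention: str = "cv"
    n_clamped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def describe(self) -> dict:
        """Serializable summary for provenance sidecars."""
        return dict(
            name=self.name,
            trait=self.trait,
            family=self.family.name,
            level=self.level,
            n_obs=self.n_obs,
            mu_terms=self.names_mu,
            disp_terms=self.names_disp,
            groups=[dict(name=g.name, side=g.side, n_levels=g.n_levels) for g in self.groups],
            species_block=None
            if self.species_block is None
            else dict(
                species=self.species_block.species,
                components=["_".join(c) for c in self.species_block.components],
            ),
            n_clamped=self.n_clamped,
        )


def _sum_to_zero(labels: pd.Series, level_order: list[str]):
    """Sum-to-zero contrast columns (last level = -sum of the others)."""
    k = len(level_order)
    cols = np.zeros((len(labels), max(k - 1, 0)))
    codes = pd.Categorical(labels, categories=level_order).codes
    if np.any(codes < 0):
        raise ValueError("labels outside the declared level order")
    for j in range(k - 1):
        cols[:, j] = (codes == j).astype(float) - (codes == k - 1).astype(float)
    names = [f"dev[{level_order[j]}]" for j in range(k - 1)]
    return cols, names


def _eco_slope_cols(data: pd.DataFrame, ecosystems: list[str]):
    D = data["richness"].to_numpy(dtype=float)
    cols = np.stack(
        [D * (data["ecosystem"] == e).to_numpy(dtype=float) for e in ecosystems], axis=1
    )
    names = [f"slope[{e}]" for e in ecosystems]
    return cols, names


def _fixed_side(data: pd.DataFrame, ecosystems: list[str], campaign: bool,
                eco_slope: bool, prefix: str):
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = [f"{prefix}0"]
    if campaign:
        campaigns = sorted(data["campaign"].unique())
        if len(campaigns) > 2:
            raise ValueError("at most two campaigns are supported")
        if len(campaigns) == 2:
            blocks.append((data["campaign"] == campaigns[1]).to_numpy(dtype=float)[:, None])
            names.append(f"{prefix}_T2")
    if len(ecosystems) > 1:
        cols, devnames = _sum_to_zero(data["ecosystem"], ecosystems)
        blocks.append(cols)
        names += [f"{prefix}_E{nm[3:]}" for nm in devnames]
    if eco_slope:
        cols, slnames = _eco_slope_cols(data, ecosystems)
        blocks.append(cols)
        names += [f"{prefix}1_E{nm[5:]}" for nm in slnames]
    return np.hstack(blocks), names


def _community_group(data: pd.DataFrame, side: str) -> HierGroup:
    levels = sorted(data["community"].unique())
    codes = pd.Categorical(data["community"], categories=levels).codes
    return HierGroup(name=f"community_{side}", side=side, levels=levels,
                     index=np.asarray(codes))


def _require_columns(data: pd.DataFrame, cols):
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing required columns: {missing}")


def _clamp_beta(y: np.ndarray):
    lo, hi = BETA_EPS, 1.0 - BETA_EPS
    n_clamped = int(np.sum((y <= lo) | (y >= hi)))
    return np.clip(y, lo, hi), n_clamped


def build(
    model_name: str,
    trait: str,
    data: pd.DataFrame,
    priors: PriorConfig | None = None,
    family: str | None = None,
    convention: str = "cv",
) -> TraitModelSpec:
    """Materialize a named candidate model for one trait on a dataset.

    For species-level models the data must already be restricted to focal
    species (see :func:`focal_species_filter`); fewer than 2 focal species is
    an error.  For ``M_dens`` the data is the per-(species, community)
    density table with a ``dens`` column.
    """
    if model_name not in _ALL_MODELS:
        raise ValueError(f"unknown model name {model_name!r}")
    priors = priors or PriorConfig()
    fam_name = family or ("gamma" if model_name == "M_dens" else TRAITS.get(trait))
    if fam_name is None:
        raise ValueError(f"unknown trait {trait!r}; pass family= explicitly")
    fam = get_family(fam_name)

    base_cols = ["ecosystem", "community", "richness", trait]
    if model_name not in ("M_dens",):
        base_cols.append("campaign")
    if model_name.startswith("M_sp") or model_name in ("M_dens", "M_means"):
        base_cols.append("species")
    _require_columns(data, base_cols)
    data = data.reset_index(drop=True)

    y = data[trait].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite response values in column {trait!r}")
    n_clamped = 0
    if fam.name == "beta":
        y, n_clamped = _clamp_beta(y)
    elif np.any(y <= 0):
        raise ValueError(f"gamma response {trait!r} must be strictly positive")

    ecosystems = sorted(data["ecosystem"].unique())
    campaign = model_name != "M_dens"
    groups: list[HierGroup] = []
    block: SpeciesBlock | None = None

    if model_name in COMMUNITY_MODELS:
        level = "community"
        mu_slope = model_name in ("M_com1", "M_com3", "M_com3p")
        disp_slope = model_name in ("M_com2", "M_com3", "M_com3p")
        X_mu, names_mu = _fixed_side(data, ecosystems, campaign, mu_slope, "beta")
        X_di, names_di = _fixed_side(data, ecosystems, campaign, disp_slope, "gamma")
        groups = [_community_group(data, "mu"), _community_group(data, "disp")]
    elif model_name == "M_means":
        level = "auxiliary"
        pooled = data.assign(ecosystem="__all__")
        X_mu, names_mu = _fixed_side(pooled, ["__all__"], campaign, False, "beta")
        X_di, names_di = _fixed_side(pooled, ["__all__"], False, False, "gamma")
        levels = sorted(data["species"].unique())
        codes = pd.Categorical(data["species"], categories=levels).codes
        groups = [HierGroup("species_mu", "mu", levels, np.asarray(codes))]
    else:
        level = "density" if model_name == "M_dens" else "species"
        species = sorted(data["species"].unique())
        if len(species) < 2:
            raise ValueError(
                f"{model_name} requires >= 2 focal species, got {len(species)}"
            )
        mu_sp_slope = model_name in ("M_sp1", "M_sp3", "M_dens")
        disp_sp_slope = model_name in ("M_sp2", "M_sp3", "M_dens")
        X_mu, names_mu = _fixed_side(data, ecosystems, campaign, not mu_sp_slope, "beta")
        X_di, names_di = _fixed_side(data, ecosystems, campaign, not disp_sp_slope, "gamma")
        groups = [_community_group(data, "mu"), _community_group(data, "disp")]
        components = [("mu", "dev"), ("disp", "dev")]
        if mu_sp_slope:
            components.append(("mu", "slope"))
        if disp_sp_slope:
            components.append(("disp", "slope"))
        codes = pd.Categorical(data["species"], categories=species).codes
        block = SpeciesBlock(
            species=species,
            index=np.asarray(codes),
            components=components,
            richness=data["richness"].to_numpy(dtype=float),
        )

    # a hierarchical deviation with a single level is absorbed by the
    # intercept and unidentifiable against its own SD; drop it
    groups = [g for g in groups if g.n_levels >= 2]

    meta_cols = [c for c in ("ecosystem", "community", "campaign", "species", "richness")
                 if c in data.columns]
    return TraitModelSpec(
        name=model_name,
        trait=trait,
        family=fam,
        level=level,
        y=y,
        X_mu=X_mu,
        X_disp=X_di,
        names_mu=names_mu,
        names_disp=names_di,
        groups=groups,
        species_block=block,
        priors=priors,
        meta=data[meta_cols].copy(),
        convention=convention,
        n_clamped=n_clamped,
    )


def focal_species_filter(records: pd.DataFrame):
    """Restrict to focal species: present in >= 4 communities of their
    ecosystem and at both extremes of that ecosystem's richness gradient.

    Returns ``(filtered_records, retained)`` where ``retained`` is the list
    of (ecosystem, species) pairs kept.  May be empty.
    """
    _require_columns(records, ["ecosystem", "community", "species", "richness"])
    retained: list[tuple[str, str]] = []
    for eco, sub in records.groupby("ecosystem", sort=True):
        lo = sub["richness"].min()
        hi = sub["richness"].max()
        occ = sub.drop_duplicates(["species", "community"])
        for sp, rows in occ.groupby("species", sort=True):
            if rows["community"].nunique() < 4:
                continue
            if (rows["richness"] == lo).any() and (rows["richness"] == hi).any():
                retained.append((eco, sp))
    keep = set(retained)
    mask = [
        (e, s) in keep
        for e, s in zip(records["ecosystem"], records["species"])
    ]
    return records[np.asarray(mask)].reset_index(drop=True), retained
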