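"""Demographic-strategy classification from posterior slope summaries.

A focal species whose density declines substantially as community richness
rises (90% credible interval of the exponentiated density mean-slope below
1) dominates species-poor communities and loses that advantage in richer
ones: a *Master-of-some* strategist.  A species whose density is stable (or
increases) across the gradient is a *Jack-of-all-trades*, typically relying
on intraspecific trait variation to persist; classification itself depends
only on the density slope, the trait-variation sign table travels with the
call.  A substantial density *increase* has no named strategy in the
framework; it is mapped to Jack with ``density_class="Increase"`` and a
warning.

``dispersion_density_covariation`` quantifies how a species' capacity to
widen/narrow its trait distribution relates to its demographic response
(the negative correlation underlying the framework's prediction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import SlopeSummary

__all__ = ["StrategyCall", "CovariationReport", "classify", "dispersion_density_covariation", "strategy_table"]


@dataclass
class StrategyCall:
    species: str
    ecosystem: str
    density_mu_slope: SlopeSummary
    trait_signs: dict[str, dict[str, int]]       # trait -> {"mu": sign, "disp": sign}
    trait_slopes: dict[str, dict[str, SlopeSummary]] = field(default_factory=dict)
    label: str = ""
    density_class: str = ""


@dataclass
class CovariationReport:
    trait: str
    n_species: int
    rho: float
    degenerate: bool
    slope: float
    intercept: float
    rho_draws: np.ndarray | None = None
    rho_ci: tuple[float, float] | None = None


def classify(
    species_slopes: dict[str, dict[str, SlopeSummary]],
    density_slope: SlopeSummary,
    species: str = "",
    ecosystem: str = "",
) -> StrategyCall:
    """Label one species from its trait slopes and density mean-slope.

    ``species_slopes`` maps trait -> {"mu": SlopeSummary, "disp":
    SlopeSummary}; signs in the attached table come from the substantiality
    flags alone.  The label is a pure function of the inputs.
    """
    if density_slope is None:
        raise ValueError("classify: missing density slope summary")
    if density_slope.sign < 0:
        density_class = "Decrease"
    elif density_slope.sign > 0:
        density_class = "Increase"
        warnings.warn(
            f"species {species or '?'}: substantial density increase has no "
            "named strategy; labeled Jack-of-all-trades",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        density_class = "Stable"
    label = "Master" if density_class == "Decrease" else "Jack"
    signs = {
        trait: {side: ss.sign for side, ss in sides.items()}
        for trait, sides in species_slopes.items()
    }
    return StrategyCall(
        species=species,
        ecosystem=ecosystem,
        density_mu_slope=density_slope,
        trait_signs=signs,
        trait_slopes=species_slopes,
        label=label,
        density_class=density_class,
    )


def dispersion_density_covariation(
    calls: list[StrategyCall],
    trait: str,
    paired_draws: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> CovariationReport:
    """Pearson correlation between exponentiated trait-dispersion slopes and
    density mean-slopes across species (posterior medians by default).

    ``paired_draws`` optionally maps species -> (dispersion-slope draws,
    density-slope draws) on the link scale; when given, a draw-wise
    distribution of the correlation is computed by pairing draw indices
    across species, yielding a 90% interval.
    """
    usable = [c for c in calls if trait in c.trait_slopes]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 species with both slopes for trait {trait!r}, got {len(usable)}"
        )
    x = np.array([c.trait_slopes[trait]["disp"].exp_median for c in usable])
    y = np.array([c.density_mu_slope.exp_median for c in usable])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CovariationReport(trait=trait, n_species=len(usable), rho=np.nan,
                                 degenerate=True, slope=np.nan, intercept=np.nan)
    rho = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    rho_draws = None
    rho_ci = None
    if paired_draws is not None:
        mats = [paired_draws[c.species] for c in usable if c.species in paired_draws]
        if len(mats) == len(usable):
            xd = np.exp(np.stack([m[0] for m in mats], axis=1))  # (draws, species)
            yd = np.exp(np.stack([m[1] for m in mats], axis=1))
            xc = xd - xd.mean(axis=1, keepdims=True)
            yc = yd - yd.mean(axis=1, keepdims=True)
            denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho_draws = (xc * yc).sum(axis=1) / denom
            rho_draws = rho_draws[np.isfinite(rho_draws)]
            if rho_draws.size:
                rho_ci = tuple(np.quantile(rho_draws, [0.05, 0.95]).tolist())
    return CovariationReport(
        trait=trait,
        n_species=len(usable),
        rho=rho,
        degenerate=False,
        slope=float(slope),
        intercept=float(intercept),
        rho_draws=rho_draws,
        rho_ci=rho_ci,
    )


_SIGN_CHR = {1: "+", -1: "-", 0: "0"}


def strategy_table(calls: list[StrategyCall]) -> pd.DataFrame:
    """Sign/strategy table: two rows per species (mean row, dispersion row)."""
    rows = []
    for c in calls:
        traits = sorted(c.trait_signs)
        for side, side_label in (("mu", "mu"), ("disp", "sigma/phi")):
            row = dict(ecosystem=c.ecosystem, species=c.species, parameter=side_label)
            for t in traits:
                row[t] = _SIGN_CHR[c.trait_signs[t][side]]
            row["density"] = c.density_class if side == "mu" else ""
            row["strategy"] = c.label if side == "mu" else ""
            rows.append(row)
    return pd.DataFrame(rows)
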