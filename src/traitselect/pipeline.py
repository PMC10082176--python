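"""End-to-end synthetic pipeline: simulate -> density -> fit -> compare -> classify.

``run_pipeline`` executes the full analysis on generated data and writes,
per configured trait, a stacking-weight table (community and species model
sets), exponentiated-slope interval tables, the strategy sign table with
Jack/Master labels, the dispersion–density covariation report, a
diagnostics sidecar and a manifest recording seeds, configuration and
package version — enough to reproduce every output.  A stage failure halts
the run with the stage name; outputs written before the failure persist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .density import density_table
from .inference import (PosteriorResult, SamplerConfig, fit,
                        fit_species_mean_model, substantiality)
from .io import PipelineConfig, save_parameters, write_records
from .model_builder import SPECIES_MODELS, build, focal_species_filter
from .model_comparison import compare_table
from .strategy import classify, dispersion_density_covariation, strategy_table
from .synthetic_data import (make_design, preset_parameters, simulate_point_plant_distances,
                             simulate_traits, species_mean_dataset)

logger = logging.getLogger("traitselect")

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # halt with the stage name, keep partials
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def _slope_prefixes(model_name: str) -> dict[str, str]:
    """Richness-slope parameter prefixes per side for a fitted model."""
    out = {}
    if model_name in ("M_com1", "M_com3", "M_com3p", "M_sp0", "M_sp2"):
        out["mu"] = "mu:beta1_E"
    if model_name in ("M_sp1", "M_sp3", "M_dens"):
        out["mu"] = "mu:species_slope"
    if model_name in ("M_com2", "M_com3", "M_com3p", "M_sp0", "M_sp1"):
        out["disp"] = "disp:gamma1_E"
    if model_name in ("M_sp2", "M_sp3", "M_dens"):
        out["disp"] = "disp:species_slope"
    return out


def _species_side_summary(result: PosteriorResult, side: str, species: str,
                          ecosystem: str):
    """Slope summary for one species on one side, falling back to that
    ecosystem's slope when the fitted model has no per-species slopes."""
    prefix = _slope_prefixes(result.spec.name).get(side)
    if prefix is None:
        return None
    if "species_slope" in prefix:
        name = f"{side}:species_slope[{species}]"
    else:
        pref = "beta1_E" if side == "mu" else "gamma1_E"
        name = f"{side}:{pref}[{ecosystem}]"
    if name not in result.param_names:
        return None
    return substantiality(result, [name])[0]


def run_pipeline(config: PipelineConfig, simulate: bool = True,
                 records: pd.DataFrame | None = None) -> Path:
    """Run the full pipeline; returns the artifact directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sampler = SamplerConfig(**config.sampler) if config.sampler else SamplerConfig()
    manifest = dict(
        version=__version__,
        config=dataclasses.asdict(config),
        outputs=[],
        stages={},
    )

    @_stage("simulate")
    def stage_simulate():
        design = make_design(config.design_config(), seed=config.seeds["design"])
        params = preset_parameters(config.preset, ecosystems=tuple(design.ecosystems))
        recs = simulate_traits(design, params, seed=config.seeds["traits"],
                               traits=list(config.traits))
        recs = simulate_point_plant_distances(recs, design, intensity=config.intensity,
                                              seed=config.seeds["distances"])
        write_records(recs, out / "records.csv")
        design.community_table().to_csv(out / "community_table.csv", index=False)
        save_parameters({t: params[t] for t in config.traits}, out / "true_parameters.yaml")
        manifest["outputs"] += ["records.csv", "community_table.csv", "true_parameters.yaml"]
        return recs

    @_stage("density")
    def stage_density(recs):
        dens = density_table(recs, by_species=True)
        dens.to_csv(out / "density.csv", index=False)
        manifest["outputs"].append("density.csv")
        return dens

    @_stage("fit_compare")
    def stage_fit_compare(recs):
        diagnostics = {}
        tables = []
        slope_rows = []
        focal, _retained = focal_species_filter(recs)
        species_results: dict[str, dict[str, PosteriorResult]] = {}
        for ti, trait in enumerate(config.traits):
            results: dict[str, PosteriorResult] = {}
            for mi, mname in enumerate(config.community_models):
                seed = config.seeds["fit"] + 101 * ti + mi
                if mname == "M_com3p":
                    fitted, _aux = fit_species_mean_model(recs, trait,
                                                          sampler_config=sampler,
                                                          seed=seed + 50)
                    data = species_mean_dataset(recs, trait, fitted)
                else:
                    data = recs
                spec = build(mname, trait, data)
                res = fit(spec, sampler_config=sampler, seed=seed)
                results[mname] = res
                diagnostics[f"{trait}:{mname}"] = res.diagnostics_dict()
            tables.append(compare_table(trait, results, config.community_models))

            sp_results: dict[str, PosteriorResult] = {}
            for mi, mname in enumerate(config.species_models):
                seed = config.seeds["fit"] + 101 * ti + 17 * (mi + 1) + 1000
                spec = build(mname, trait, focal)
                res = fit(spec, sampler_config=sampler, seed=seed)
                sp_results[mname] = res
                diagnostics[f"{trait}:{mname}"] = res.diagnostics_dict()
            if sp_results:
                tables.append(compare_table(trait, sp_results,
                                            list(config.species_models)))
            species_results[trait] = sp_results

            # figure-4 style interval table from the full community model
            full = results.get("M_com3") or results[max(results)]
            for side, prefix in _slope_prefixes(full.spec.name).items():
                for ss in substantiality(full, prefix):
                    slope_rows.append(dict(trait=trait, model=full.spec.name,
                                           side=side, parameter=ss.parameter,
                                           exp_median=ss.exp_median, ci_low=ss.ci_low,
                                           ci_high=ss.ci_high, substantial=ss.substantial,
                                           sign=ss.sign))
        weights = pd.concat(tables, ignore_index=True)
        weights.to_csv(out / "stacking_weights.csv", index=False)
        pd.DataFrame(slope_rows).to_csv(out / "slope_intervals.csv", index=False)
        (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
        manifest["outputs"] += ["stacking_weights.csv", "slope_intervals.csv",
                                "diagnostics.json"]
        return weights, species_results, focal

    @_stage("classify")
    def stage_classify(dens, weights, species_results, focal):
        # density model over focal species
        sp_dens = dens[(dens["species"] != "__all__")
                       & dens["species"].isin(focal["species"].unique())].copy()
        spec = build("M_dens", "dens", sp_dens)
        dres = fit(spec, sampler_config=sampler, seed=config.seeds["fit"] + 9000)
        eco_of = dict(zip(focal["species"], focal["ecosystem"]))
        calls = []
        for sp in sorted(sp_dens["species"].unique()):
            dens_ss = substantiality(dres, [f"mu:species_slope[{sp}]"])[0]
            trait_slopes = {}
            for trait, sp_results in species_results.items():
                w = weights[(weights["trait"] == trait)
                            & weights["model"].isin(SPECIES_MODELS) & weights["best"]]
                best_name = w["model"].iloc[0] if len(w) else None
                if best_name is None or best_name not in sp_results:
                    continue
                res = sp_results[best_name]
                sides = {}
                for side in ("mu", "disp"):
                    ss = _species_side_summary(res, side, sp, eco_of.get(sp, ""))
                    if ss is not None:
                        sides[side] = ss
                if len(sides) == 2:
                    trait_slopes[trait] = sides
            calls.append(classify(trait_slopes, dens_ss, species=sp,
                                  ecosystem=eco_of.get(sp, "")))
        table2 = strategy_table(calls)
        table2.to_csv(out / "strategy_table.csv", index=False)
        manifest["outputs"].append("strategy_table.csv")
        cov_rows = []
        for trait in config.traits:
            try:
                rep = dispersion_density_covariation(calls, trait)
                cov_rows.append(dict(trait=trait, n_species=rep.n_species, rho=rep.rho,
                                     degenerate=rep.degenerate, slope=rep.slope,
                                     intercept=rep.intercept))
            except ValueError as exc:
                cov_rows.append(dict(trait=trait, n_species=len(calls), rho=np.nan,
                                     degenerate=True, slope=np.nan, intercept=np.nan,
                                     note=str(exc)))
        pd.DataFrame(cov_rows).to_csv(out / "covariation.csv", index=False)
        manifest["outputs"].append("covariation.csv")
        return calls

    recs = stage_simulate() if simulate else records
    if recs is None:
        raise PipelineError("simulate", ValueError("no records provided and simulate=False"))
    dens = stage_density(recs)
    weights, species_results, focal = stage_fit_compare(recs)
    stage_classify(dens, weights, species_results, focal)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
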