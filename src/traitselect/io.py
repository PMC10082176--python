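"""Readers, writers and configuration for the pipeline.

The interchange format is UTF-8 CSV with a header row and "." decimals (the
field data this design emulates is tabular).  ``read_records`` validates
every row against the trait domains — Gamma traits strictly positive, LDMC
inside (0,1) with boundary values clamped to ``1e-4`` / ``1 - 1e-4`` and
counted, distances finite and positive — and rejects violations with line
numbers (line 1 = header, data starts at line 2).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_builder import BETA_EPS
from .synthetic_data import TRAITS, DesignConfig, TraitParams

logger = logging.getLogger("traitselect")

__all__ = [
    "REQUIRED_COLUMNS",
    "read_records",
    "write_records",
    "save_parameters",
    "load_parameters",
    "PipelineConfig",
]

REQUIRED_COLUMNS = ("ecosystem", "community", "campaign", "species", "distance_cm") + tuple(TRAITS)


def read_records(path, community_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate an individual-level table.

    Returns typed records; raises ``ValueError`` naming the first offending
    line for missing columns, unparseable numerics or domain violations.
    A ``richness`` column is merged from ``community_table`` when absent.
    """
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    numeric = ["distance_cm", *TRAITS]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: unparseable value in column {col!r} at line {int(bad[0]) + 2}"
            )
        if parsed.isna().any():
            raise ValueError(
                f"{path}: missing value in column {col!r} at line "
                f"{int(df.index[parsed.isna()][0]) + 2}"
            )
        df[col] = parsed.astype(float)

    for col in ("distance_cm", *(t for t, fam in TRAITS.items() if fam == "gamma")):
        bad = df.index[(df[col] <= 0) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValueError(
                f"{path}: non-positive {col!r} at line {int(bad[0]) + 2}"
            )

    ldmc = df["LDMC"]
    bad = df.index[(ldmc < 0) | (ldmc > 1)]
    if len(bad):
        raise ValueError(f"{path}: LDMC outside [0, 1] at line {int(bad[0]) + 2}")
    at_bound = (ldmc <= BETA_EPS) | (ldmc >= 1 - BETA_EPS)
    n_clamped = int(at_bound.sum())
    if n_clamped:
        df["LDMC"] = ldmc.clip(BETA_EPS, 1 - BETA_EPS)
        logger.info("read_records: clamped %d boundary LDMC values to (%g, %g)",
                    n_clamped, BETA_EPS, 1 - BETA_EPS)
    df.attrs["n_ldmc_clamped"] = n_clamped

    if "richness" not in df.columns:
        if community_table is None:
            raise ValueError(
                f"{path}: no richness column and no community table to merge it from"
            )
        df = df.merge(community_table[["community", "richness"]], on="community",
                      how="left", validate="many_to_one")
        if df["richness"].isna().any():
            missing_com = df.loc[df["richness"].isna(), "community"].iloc[0]
            raise ValueError(f"{path}: community {missing_com!r} absent from community table")
    df["richness"] = df["richness"].astype(int)
    return df


def write_records(records: pd.DataFrame, path) -> None:
    """Write records as canonical UTF-8 CSV (stable column order, '.' decimals)."""
    lead = [c for c in ("ecosystem", "community", "campaign", "harvester", "species",
                        "richness", "area_m2", "flowering", "distance_cm", *TRAITS)
            if c in records.columns]
    rest = [c for c in records.columns if c not in lead]
    records[lead + rest].to_csv(path, index=False, encoding="utf-8")


def save_parameters(params: dict[str, TraitParams], path) -> None:
    doc = {trait: tp.to_dict() for trait, tp in params.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def load_parameters(path) -> dict[str, TraitParams]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return {trait: TraitParams.from_dict(d) for trait, d in doc.items()}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full synthetic run.

    Every stochastic stage has its own explicit seed; a missing seed is a
    configuration error caught before any computation.
    """

    out_dir: str = "pipeline_out"
    preset: str = "bog-like"
    intensity: float = 200.0
    traits: list[str] = field(default_factory=lambda: ["EL", "LDMC"])
    community_models: list[str] = field(
        default_factory=lambda: ["M_com0", "M_com1", "M_com2", "M_com3", "M_com3p"]
    )
    species_models: list[str] = field(
        default_factory=lambda: ["M_sp0", "M_sp1", "M_sp2", "M_sp3"]
    )
    design: dict = field(default_factory=dict)         # DesignConfig overrides
    sampler: dict = field(default_factory=dict)        # SamplerConfig overrides
    seeds: dict = field(
        default_factory=lambda: dict(design=1, traits=2, distances=3, fit=4)
    )

    REQUIRED_SEEDS = ("design", "traits", "distances", "fit")

    def validate(self) -> None:
        missing = [k for k in self.REQUIRED_SEEDS if k not in self.seeds]
        if missing:
            raise ValueError(f"pipeline config missing seeds for stages: {missing}")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits in config: {sorted(unknown)}")

    def design_config(self) -> DesignConfig:
        fields = {f.name for f in dataclasses.fields(DesignConfig)}
        unknown = set(self.design) - fields
        if unknown:
            raise ValueError(f"unknown design settings: {sorted(unknown)}")
        kwargs = dict(self.design)
        for key in ("ecosystems", "communities_per_ecosystem", "richness_range",
                    "campaigns", "area_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return DesignConfig(**kwargs)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - fields
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg
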