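import numpy as np
import pandas as pd
import pytest

import traitselect as ts
from traitselect.inference import SamplerConfig, fit
from traitselect.model_builder import build, focal_species_filter

TOY_ECOSYSTEMS = ("bog", "fen")


def toy_config(**overrides):
    """Reduced 2-ecosystem x 4-community x 30-individual design for fast fits."""
    kwargs = dict(
        ecosystems=TOY_ECOSYSTEMS,
        communities_per_ecosystem=(4, 4),
        n_per_community=30,
        pool_size=12,
        richness_range=(2, 10),
        richness_min_per_ecosystem=(2, 3),
    )
    kwargs.update(overrides)
    return ts.DesignConfig(**kwargs)


@pytest.fixture(scope="session")
def toy_design():
    return ts.make_design(toy_config(), seed=3)


@pytest.fixture(scope="session")
def toy_params():
    return ts.preset_parameters(ecosystems=TOY_ECOSYSTEMS)


@pytest.fixture(scope="session")
def toy_records(toy_design, toy_params):
    recs = ts.simulate_traits(toy_design, toy_params, seed=4)
    return ts.simulate_point_plant_distances(recs, toy_design, intensity=200.0, seed=5)


@pytest.fixture(scope="session")
def toy_focal(toy_records):
    records, retained = focal_species_filter(toy_records)
    return records, retained


@pytest.fixture(scope="session")
def intercept_gamma_data():
    """500 draws from Gamma(mu=10, sigma=0.2) in a single community."""
    rng = np.random.default_rng(0)
    y = ts.distributions.sample("gamma", 10.0, 0.2, n=500, rng=rng)
    return pd.DataFrame(
        dict(ecosystem="e1", community="c1", campaign="T1", richness=5, EL=y)
    )


@pytest.fixture(scope="session")
def intercept_gamma_fit(intercept_gamma_data):
    spec = build("M_com0", "EL", intercept_gamma_data)
    return fit(spec, SamplerConfig(chains=2, warmup=500, samples=750), seed=1)
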